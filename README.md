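# tacpk2pd

Dual-matrix population pharmacokinetics / pharmacodynamics of tacrolimus
in liver transplantation: whole-blood **and** intracellular (PBMC)
concentrations, nonparametric population estimation, pharmacogenetic
association statistics, calcineurin-inhibition modelling, and Monte-Carlo
probability of target attainment.

## The problem

Tacrolimus dosing is steered by whole-blood trough concentrations
(therapeutic drug monitoring toward 4–10 ng/mL in liver recipients), yet
the drug acts *inside* lymphocytes, where it inhibits calcineurin (CaN).
Whole-blood and intra-PBMC exposures correlate only moderately
(r² ≈ 0.5), partly because efflux-transporter genetics (ABCB1, notably
1199G>A) shape the blood-to-cell partitioning. This package implements
the full analysis chain needed to study that question, driven entirely by
a calibrated synthetic cohort generator (no patient data are shipped):

* `data_model_io` — cohort data model and a NONMEM-flavoured long-format
  CSV dialect (`ID, TIME_H, AMT, DV, MATRIX, MDV` + a subjects table);
* `pk_model` — two-compartment disposition with **double-gamma** oral
  absorption, solved in closed form (gamma–exponential convolution), with
  the assay-error model σ(C) = assay_sd(C) + λ;
* `np_fit` — nonparametric population estimation (discrete support
  points + weights by multiplicative EM over a Sobol grid with
  per-subject candidates), posteriors, AIC, goodness-of-fit diagnostics,
  visual predictive checks, covariate screening;
* `exposure` — C0 / Cmax / Tmax / AUC0-12 / CL/F, the intracellular
  diffusion ratio, CaN activity metrics (AUA, maximal % inhibition), and
  Shapiro-gated Pearson/Spearman correlation;
* `pgx` — exact Hardy-Weinberg testing, 3-locus ABCB1 haplotype EM,
  TTT-diplotype classes, Mann-Whitney / Kruskal-Wallis associations with
  Bonferroni post-hocs;
* `pkpd` — the inhibitory concentration-effect curve
  `E(c) = I_min + (I_max − I_min)/(1 + c/IC50)` with fitting and exact
  ICx inversion;
* `pta` — Monte-Carlo probability that the intra-PBMC peak reaches an
  inhibitory target (IC50 = 100, IC37 = 65 pg per million cells) within
  each whole-blood trough stratum;
* `synthetic_data` — the cohort generator (covariates, haplotypes,
  titration emulation, dual-matrix profiles, CaN activity) calibrated to
  the published cohort summaries.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from tacpk2pd.synthetic_data import default_population, generate_cohort
from tacpk2pd.exposure import nca_metrics, pd_metrics
from tacpk2pd.pta import PTAConfig, simulate_profiles, attainment

cohort = generate_cohort(default_population(), seed=7)
rows = [nca_metrics(s)[0] for s in cohort.subjects]
med = lambda xs: float(np.median([x for x in xs if x is not None]))
print(f"median dose        : {med([m.dose for m in rows]):.1f} mg")
print(f"median C0 (WB)     : {med([m.c0_wb for m in rows]):.1f} ng/mL")
print(f"median AUC0-12 (WB): {med([m.auc_wb for m in rows]):.1f} ng.h/mL")
print(f"median diffusion ratio: {med([m.diffusion_ratio for m in rows]):.1f}")

cfg = PTAConfig(n_profiles=1000, seed=7)
res = attainment(simulate_profiles(default_population(), cfg), cfg)
for r in res.rows:
    if r.target == 100.0 and r.hi is not None:
        print(f"P(Cmax_PBMC >= 100 | trough in [{r.lo:g},{r.hi:g})) = {r.probability:.2f}")
```

prints (n = 32 subjects, raw noisy samples):

```
median dose        : 1.5 mg
median C0 (WB)     : 4.9 ng/mL
median AUC0-12 (WB): 110.6 ng.h/mL
median diffusion ratio: 25.4
P(Cmax_PBMC >= 100 | trough in [0,4)) = 0.04
P(Cmax_PBMC >= 100 | trough in [4,6)) = 0.16
P(Cmax_PBMC >= 100 | trough in [6,10)) = 0.38
```

Read: a typical maintenance dose of 1.5 mg q12h keeps whole-blood
exposure on target, the intracellular-to-blood partitioning ratio sits
near 25, and even in the recommended 6–10 ng/mL trough window only about
a third of simulated profiles reach the intracellular concentration that
halves calcineurin activity — whole-blood monitoring alone does not
guarantee an inhibitory concentration at the drug's site of action.

A thin CLI mirrors the library:

```bash
tacpk2pd generate --n 32 --seed 7 --out-prefix cohort
tacpk2pd validate cohort_obs.csv cohort_subj.csv
tacpk2pd fit cohort_obs.csv cohort_subj.csv --out model.json
tacpk2pd nca cohort_obs.csv cohort_subj.csv --out metrics.csv
tacpk2pd pkpd --metrics metrics.csv --matrix PBMC --out inhibition.json
tacpk2pd pta --n 1000 --seed 7 --out pta.csv
```

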
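"""Pharmacogenetic statistics.

Hardy-Weinberg exact testing, EM haplotype inference over the three-locus
ABCB1 system (3435C>T / 1236C>T / 2677G>T/A), TTT-diplotype
classification, and genotype-exposure association testing with Bonferroni
correction for post-hoc comparisons.

The 2677 locus is triallelic (G>T/A); the rare A allele is pooled with T
for haplotype inference and TTT classification (it marks the same
non-wild-type axis), while raw genotype tables keep it distinct.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ABCB1_LOCI",
    "HaplotypeResult",
    "AssociationResult",
    "GroupSummary",
    "hwe_exact",
    "haplotype_em",
    "classify_ttt",
    "genotype_association",
    "pool_2677",
]

ABCB1_LOCI = ("ABCB1_3435", "ABCB1_1236", "ABCB1_2677")

#: variant ("T-axis") allele per locus of the TTT haplotype
_VARIANT = ("T", "T", "T")
_WILD = ("C", "C", "G")

#: exact Mann-Whitney up to this combined sample size (subgroups are tiny)
_EXACT_MW_N = 20


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic SNP.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    Monomorphic samples return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total count must be > 0")
    n_A = 2 * n_AA + n_Aa
    if n_A == 0 or n_A == 2 * n:
        return 1.0
    n_minor = min(n_A, 2 * n - n_A)
    # heterozygote counts share the parity of the minor allele count
    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = []
    for h in hets:
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n - n_hom_minor - h
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(n_hom_minor + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_hom_major + 1)
            + h * math.log(2.0)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def pool_2677(call: str) -> str:
    """Recode the triallelic 2677 call onto the biallelic G/T axis (A -> T)."""
    return "".join(sorted(call.replace("A", "T")))


@dataclass(frozen=True)
class HaplotypeResult:
    frequencies: dict  # haplotype tuple -> frequency
    diplotypes: tuple  # per subject: ((hap1, hap2), posterior probability)
    loglik: float
    n_iter: int
    excluded: tuple = ()  # indices of subjects with missing calls


def _consistent_diplotypes(triple):
    """Unordered haplotype pairs consistent with an unphased 3-locus call.

    ``triple`` holds one (allele, allele) pair per locus.
    """
    pairs = set()
    het = [i for i, (x, y) in enumerate(triple) if x != y]
    for assignment in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = [], []
        k = 0
        for i, (x, y) in enumerate(triple):
            if x == y:
                h1.append(x)
                h2.append(x)
            else:
                flip = assignment[k]
                h1.append((x, y)[flip])
                h2.append((x, y)[1 - flip])
                k += 1
        pairs.add(tuple(sorted((tuple(h1), tuple(h2)))))
    return sorted(pairs)


def haplotype_em(
    genotype_triples,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HaplotypeResult:
    """Maximum-likelihood haplotype frequencies by EM over unphased calls.

    ``genotype_triples`` is one entry per subject: three (allele, allele)
    pairs in locus order 3435/1236/2677, with 2677 already pooled onto the
    G/T axis (see :func:`pool_2677`).  Subjects with a missing locus
    (``None``) are excluded and reported.

    The E-step distributes each subject's mass over phase-consistent
    diplotypes in proportion to current frequency products (factor 2 for
    heterozygous pairs); the M-step re-estimates frequencies from expected
    haplotype counts.  Converges when the largest frequency change is
    below ``tol``.
    """
    included, excluded = [], []
    for i, triple in enumerate(genotype_triples):
        if triple is None or any(loc is None for loc in triple):
            excluded.append(i)
        else:
            included.append((i, _consistent_diplotypes(triple)))
    if not included:
        raise ValueError("no subject has complete three-locus genotypes")

    haplotypes = sorted({h for _, pairs in included for pair in pairs for h in pair})
    freq = {h: 1.0 / len(haplotypes) for h in haplotypes}
    n = len(included)
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        counts = {h: 0.0 for h in haplotypes}
        loglik = 0.0
        for _, pairs in included:
            ws = np.array(
                [(1.0 if h1 == h2 else 2.0) * freq[h1] * freq[h2] for h1, h2 in pairs]
            )
            tot = ws.sum()
            loglik += math.log(tot) if tot > 0 else -math.inf
            if tot <= 0:
                continue
            for (h1, h2), w in zip(pairs, ws / tot):
                counts[h1] += w
                counts[h2] += w
        new = {h: counts[h] / (2.0 * n) for h in haplotypes}
        delta = max(abs(new[h] - freq[h]) for h in haplotypes)
        freq = new
        if delta < tol:
            break

    diplotypes = []
    for _, pairs in included:
        ws = np.array(
            [(1.0 if h1 == h2 else 2.0) * freq[h1] * freq[h2] for h1, h2 in pairs]
        )
        tot = ws.sum()
        j = int(np.argmax(ws))
        diplotypes.append((pairs[j], float(ws[j] / tot) if tot > 0 else float("nan")))

    return HaplotypeResult(
        frequencies={h: f for h, f in freq.items()},
        diplotypes=tuple(diplotypes),
        loglik=float(loglik),
        n_iter=it,
        excluded=tuple(excluded),
    )


def classify_ttt(diplotype) -> str:
    """Classify a 3435/1236/2677 diplotype by its TTT-haplotype load."""
    h1, h2 = diplotype
    n_ttt = (tuple(h1) == _VARIANT) + (tuple(h2) == _VARIANT)
    return {2: "HomTTT", 1: "HetTTT", 0: "other"}[n_ttt]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class PairwiseTest:
    labels: tuple
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class AssociationResult:
    metric: str
    grouping: str
    test: str  # "mann-whitney" | "kruskal-wallis"
    groups: tuple  # GroupSummary per group
    p_raw: float
    p_adjusted: float
    family_size: int
    significant: bool
    posthoc: tuple = field(default=())
    findings: tuple = field(default=())


def _mann_whitney(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 1.0  # every value tied: no evidence by convention
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= _EXACT_MW_N and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def genotype_association(
    values,
    groups,
    metric: str = "metric",
    grouping: str = "genotype",
    family_size: int | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Nonparametric association between an exposure metric and a grouping.

    Two groups -> two-sided Mann-Whitney (exact when the combined n is
    small and tie-free, normal approximation with tie correction
    otherwise).  Three or more -> Kruskal-Wallis followed by pairwise
    Mann-Whitney with Bonferroni correction over the pairs;
    ``family_size`` overrides the correction family (default: the number
    of post-hoc pairs, 1 for a two-group comparison).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must have the same length")
    findings = []
    by = {}
    for lbl in sorted({str(g) for g in groups}):
        v = values[groups.astype(str) == lbl]
        v = v[np.isfinite(v)]
        if v.size == 0:
            findings.append(f"group {lbl!r} empty; dropped")
            continue
        by[lbl] = v
    if len(by) < 2:
        raise ValueError("need at least 2 non-empty groups")

    summaries = tuple(
        GroupSummary(lbl, int(v.size), float(np.median(v)), float(v.min()), float(v.max()))
        for lbl, v in by.items()
    )
    labels = list(by)
    posthoc = ()
    if len(by) == 2:
        test = "mann-whitney"
        p_raw = _mann_whitney(by[labels[0]], by[labels[1]])
        fam = family_size if family_size is not None else 1
    else:
        test = "kruskal-wallis"
        if np.ptp(values[np.isfinite(values)]) == 0.0:
            p_raw = 1.0
        else:
            p_raw = float(stats.kruskal(*by.values()).pvalue)
        pairs = list(itertools.combinations(labels, 2))
        fam = family_size if family_size is not None else len(pairs)
        posthoc = tuple(
            PairwiseTest(
                (a, b),
                (p := _mann_whitney(by[a], by[b])),
                min(1.0, p * fam),
            )
            for a, b in pairs
        )
    p_adj = min(1.0, p_raw * (family_size if family_size is not None else 1)) \
        if len(by) == 2 else p_raw
    return AssociationResult(
        metric=metric,
        grouping=grouping,
        test=test,
        groups=summaries,
        p_raw=p_raw,
        p_adjusted=p_adj,
        family_size=fam,
        significant=p_adj < alpha,
        posthoc=posthoc,
        findings=tuple(findings),
    )
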
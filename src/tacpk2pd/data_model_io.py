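"""Cohort data model and the long-format CSV dialect used by every stage.

Two files describe a cohort, in a NONMEM-flavoured long format (the
de-facto pharmacometric interchange shape):

* an *observations* CSV with columns ``ID, TIME_H, AMT, DV, MATRIX, MDV``
  — rows with ``AMT > 0`` are dose events (mg), rows with ``MDV == 0`` are
  observations with ``MATRIX`` one of ``WB`` (ng/mL), ``PBMC`` (pg per
  million cells) or ``CAN`` (calcineurin activity, pmol/min per million
  PBMC);
* a *subjects* CSV with one row per ``ID`` carrying covariates, the basal
  calcineurin activity, genotype calls for recipient (``R_``) and donor
  (``D_``) and, for generator-produced cohorts, the true simulation
  parameters (``TRUE_`` columns, provenance only).

Times are hours internally; ``TIME_MIN`` is accepted on input and
converted.  The ``t = 0`` sample is the predose (trough) observation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .pk_model import PARAM_NAMES, PKParameterVector

__all__ = [
    "MATRICES",
    "SNPS",
    "SNP_ALLELES",
    "DoseEvent",
    "ConcentrationSeries",
    "CalcineurinSeries",
    "GenotypeRecord",
    "CovariateRecord",
    "Subject",
    "Cohort",
    "Finding",
    "SchemaError",
    "ReferentialError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

MATRICES = ("WB", "PBMC", "CAN")

SNPS = ("ABCB1_3435", "ABCB1_1236", "ABCB1_2677", "ABCB1_1199", "CYP3A4_22", "CYP3A5_3")

#: allowed alleles per SNP (2677 is triallelic G>T/A)
SNP_ALLELES = {
    "ABCB1_3435": "CT",
    "ABCB1_1236": "CT",
    "ABCB1_2677": "GTA",
    "ABCB1_1199": "GA",
    "CYP3A4_22": "CT",
    "CYP3A5_3": "AG",
}


class SchemaError(ValueError):
    """A required column is missing or a value violates the dialect."""


class ReferentialError(KeyError):
    """An observation refers to a subject absent from the subjects table."""


@dataclass(frozen=True)
class DoseEvent:
    """Oral dose: time in hours since first dose, amount in mg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0.0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if not self.amount > 0.0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Concentration-time series within one 0-12 h dosing interval."""

    matrix: str
    times: tuple = ()
    values: tuple = ()

    def __post_init__(self) -> None:
        if self.matrix not in ("WB", "PBMC"):
            raise ValueError(f"matrix must be WB or PBMC, got {self.matrix!r}")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CalcineurinSeries:
    """Calcineurin activity over the interval plus the pre-treatment basal."""

    times: tuple = ()
    activity: tuple = ()
    basal: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.activity):
            raise ValueError("times and activity must have the same length")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "activity", tuple(float(v) for v in self.activity))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GenotypeRecord:
    """Unphased two-allele call, order-normalized alphabetically."""

    origin: str
    snp: str
    call: str

    def __post_init__(self) -> None:
        if self.origin not in ("recipient", "donor"):
            raise ValueError(f"origin must be recipient or donor, got {self.origin!r}")
        if self.snp not in SNPS:
            raise ValueError(f"unknown SNP {self.snp!r}")
        call = "".join(sorted(self.call.upper()))
        if len(call) != 2 or any(a not in SNP_ALLELES[self.snp] for a in call):
            raise ValueError(
                f"invalid call {self.call!r} for {self.snp} "
                f"(alleles {SNP_ALLELES[self.snp]})"
            )
        object.__setattr__(self, "call", call)


@dataclass(frozen=True)
class CovariateRecord:
    age: float
    sex: str
    weight: float
    albumin: float
    hematocrit: float
    pbmc_count: float
    days_post_tx: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        for name in ("age", "weight", "albumin", "hematocrit", "pbmc_count", "days_post_tx"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0")
        # percent accepted on input, stored as a fraction
        if self.hematocrit >= 1.0:
            object.__setattr__(self, "hematocrit", self.hematocrit / 100.0)


@dataclass(frozen=True)
class Subject:
    id: str
    doses: tuple = ()
    wb: ConcentrationSeries = field(default_factory=lambda: ConcentrationSeries("WB"))
    pbmc: ConcentrationSeries = field(default_factory=lambda: ConcentrationSeries("PBMC"))
    can: CalcineurinSeries | None = None
    covariates: CovariateRecord | None = None
    genotypes: tuple = ()
    true_params: PKParameterVector | None = None

    def __post_init__(self) -> None:
        if self.wb.matrix != "WB" or self.pbmc.matrix != "PBMC":
            raise ValueError("series matrices must match their slots")
        times = [d.time for d in self.doses]
        if times != sorted(times) or len(set(times)) != len(times):
            raise ValueError("doses must be sorted ascending with no duplicate times")
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "genotypes", tuple(self.genotypes))

    @property
    def dose_amount(self) -> float | None:
        """Maintenance dose (mg) — the amount of the last dose event."""
        return self.doses[-1].amount if self.doses else None

    def genotype(self, origin: str, snp: str) -> str | None:
        for g in self.genotypes:
            if g.origin == origin and g.snp == snp:
                return g.call
        return None


@dataclass(frozen=True)
class Cohort:
    subjects: tuple = ()
    meta: tuple = ()  # ordered (key, value) provenance pairs

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "meta", tuple(tuple(kv) for kv in self.meta))

    def __len__(self) -> int:
        return len(self.subjects)

    def require_nonempty(self, what: str = "analysis") -> None:
        if not self.subjects:
            raise ValueError(f"cohort is empty; {what} requires at least one subject")


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    subject_id: str | None
    message: str


# ---------------------------------------------------------------------------
# CSV dialect

_OBS_COLUMNS = ("ID", "TIME_H", "AMT", "DV", "MATRIX", "MDV")
_COV_COLUMNS = (
    "AGE", "SEX", "WEIGHT", "ALBUMIN", "HEMATOCRIT", "PBMC_COUNT", "DAYS_POST_TX",
)
_TRUE_COLUMNS = tuple(f"TRUE_{n.upper()}" for n in PARAM_NAMES)


def _geno_columns():
    cols = []
    for origin, prefix in (("recipient", "R"), ("donor", "D")):
        for snp in SNPS:
            cols.append((f"{prefix}_{snp}", origin, snp))
    return cols


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        if math.isnan(x):
            return ""
        return repr(x)  # shortest round-trip representation
    return str(x)


def write_cohort(cohort: Cohort, obs_path, subj_path) -> None:
    """Write the two cohort CSVs with deterministic row/column order.

    Rows are sorted by ID then TIME_H (dose events before observations at
    equal times); floats use their shortest round-trip representation so
    two writes of the same cohort are byte-identical and
    ``read_cohort(write_cohort(c)) == c``.
    """
    subjects = sorted(cohort.subjects, key=lambda s: s.id)
    has_true = any(s.true_params is not None for s in subjects)

    with open(obs_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_OBS_COLUMNS)
        for s in subjects:
            rows = []
            for d in s.doses:
                rows.append((d.time, 0, _fmt(d.amount), "", "", 1))
            for series, matrix in ((s.wb, "WB"), (s.pbmc, "PBMC")):
                for t, v in zip(series.times, series.values):
                    rows.append((t, 1, "", _fmt(v), matrix, 0))
            if s.can is not None:
                for t, v in zip(s.can.times, s.can.activity):
                    rows.append((t, 1, "", _fmt(v), "CAN", 0))
            rows.sort(key=lambda r: (r[0], r[1], r[4]))
            for t, _, amt, dv, matrix, mdv in rows:
                w.writerow([s.id, _fmt(float(t)), amt, dv, matrix, mdv])

    geno_cols = _geno_columns()
    header = ["ID", *(c for c, _, _ in geno_cols), *_COV_COLUMNS, "CAN_BASAL"]
    if has_true:
        header += list(_TRUE_COLUMNS)
    with open(subj_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in subjects:
            row = [s.id]
            for _, origin, snp in geno_cols:
                row.append(s.genotype(origin, snp) or "")
            c = s.covariates
            if c is None:
                row += [""] * len(_COV_COLUMNS)
            else:
                row += [_fmt(c.age), c.sex, _fmt(c.weight), _fmt(c.albumin),
                        _fmt(c.hematocrit), _fmt(c.pbmc_count), _fmt(c.days_post_tx)]
            row.append(_fmt(s.can.basal) if s.can is not None else "")
            if has_true:
                if s.true_params is None:
                    row += [""] * len(_TRUE_COLUMNS)
                else:
                    row += [_fmt(float(v)) for v in s.true_params.as_array()]
            w.writerow(row)


def read_cohort(obs_path, subj_path) -> Cohort:
    """Read and validate a cohort from the observations/subjects CSV pair."""
    obs = pd.read_csv(obs_path, dtype=str, keep_default_na=False)
    subj = pd.read_csv(subj_path, dtype=str, keep_default_na=False)

    cols = set(obs.columns)
    if "TIME_H" not in cols and "TIME_MIN" in cols:
        obs = obs.rename(columns={"TIME_MIN": "TIME_H"})
        obs["TIME_H"] = [str(float(t) / 60.0) for t in obs["TIME_H"]]
        cols = set(obs.columns)
    for c in _OBS_COLUMNS:
        if c not in cols:
            raise SchemaError(f"observations CSV is missing required column {c!r}")
    if "ID" not in subj.columns:
        raise SchemaError("subjects CSV is missing required column 'ID'")

    known_ids = list(subj["ID"])
    if len(set(known_ids)) != len(known_ids):
        raise SchemaError("subjects CSV has duplicate IDs")

    per = {sid: {"doses": [], "WB": [], "PBMC": [], "CAN": []} for sid in known_ids}
    for i, row in obs.iterrows():
        sid = row["ID"]
        if sid not in per:
            raise ReferentialError(
                f"observation row {i} refers to unknown subject ID {sid!r}"
            )
        t = float(row["TIME_H"])
        amt = row["AMT"].strip()
        if amt not in ("", "0", "0.0") and float(amt) > 0:
            per[sid]["doses"].append(DoseEvent(t, float(amt)))
            continue
        if str(row["MDV"]).strip() in ("1", "1.0"):
            continue
        matrix = row["MATRIX"].strip()
        if matrix not in MATRICES:
            raise SchemaError(
                f"observation row {i} (ID {sid!r}, TIME_H {t}): unknown MATRIX "
                f"{matrix!r}, expected one of {MATRICES}"
            )
        per[sid][matrix].append((t, float(row["DV"])))

    subjects = []
    for _, row in subj.iterrows():
        sid = row["ID"]
        d = per[sid]
        genotypes = []
        for col, origin, snp in _geno_columns():
            call = str(row.get(col, "")).strip()
            if call:
                genotypes.append(GenotypeRecord(origin, snp, call))
        cov = None
        if str(row.get("AGE", "")).strip():
            cov = CovariateRecord(
                age=float(row["AGE"]), sex=str(row["SEX"]).strip(),
                weight=float(row["WEIGHT"]), albumin=float(row["ALBUMIN"]),
                hematocrit=float(row["HEMATOCRIT"]),
                pbmc_count=float(row["PBMC_COUNT"]),
                days_post_tx=float(row["DAYS_POST_TX"]),
            )
        can = None
        basal = str(row.get("CAN_BASAL", "")).strip()
        if d["CAN"] or basal:
            pts = sorted(d["CAN"])
            can = CalcineurinSeries(
                times=tuple(t for t, _ in pts),
                activity=tuple(v for _, v in pts),
                basal=float(basal) if basal else None,
            )
        tp = None
        if all(str(row.get(c, "")).strip() for c in _TRUE_COLUMNS):
            tp = PKParameterVector.from_array(
                [float(row[c]) for c in _TRUE_COLUMNS]
            )
        wb_pts = sorted(d["WB"])
        pb_pts = sorted(d["PBMC"])
        subjects.append(
            Subject(
                id=sid,
                doses=tuple(sorted(d["doses"], key=lambda e: e.time)),
                wb=ConcentrationSeries("WB", tuple(t for t, _ in wb_pts),
                                       tuple(v for _, v in wb_pts)),
                pbmc=ConcentrationSeries("PBMC", tuple(t for t, _ in pb_pts),
                                         tuple(v for _, v in pb_pts)),
                can=can,
                covariates=cov,
                genotypes=tuple(genotypes),
                true_params=tp,
            )
        )
    return Cohort(subjects=tuple(subjects))


def validate_cohort(cohort: Cohort) -> list[Finding]:
    """Check a cohort against the sampling-design contract.

    Pure: never raises, never mutates; repeated calls return identical
    findings.
    """
    findings: list[Finding] = []

    def add(level, sid, msg):
        findings.append(Finding(level, sid, msg))

    if not cohort.subjects:
        add("warning", None, "cohort has no subjects")
    for s in cohort.subjects:
        for series, label in ((s.wb, "WB"), (s.pbmc, "PBMC")):
            times, values = series.times, series.values
            if not times:
                add("warning", s.id, f"{label} series is empty")
                continue
            if any(t < 0.0 or t > 12.0 for t in times):
                add("error", s.id, f"{label} sample time outside [0, 12] h")
            if list(times) != sorted(set(times)):
                add("error", s.id, f"{label} sample times not strictly increasing")
            if any(v < 0.0 for v in values):
                add("error", s.id, f"{label} has negative concentrations")
        if s.can is not None:
            if s.can.basal is None:
                add("error", s.id, "CAN series present without basal activity")
            elif not s.can.basal > 0.0:
                add("error", s.id, "CAN basal activity must be > 0")
            if any(v <= 0.0 for v in s.can.activity):
                add("error", s.id, "CAN activity values must be > 0")
            if any(t < 0.0 or t > 12.0 for t in s.can.times):
                add("error", s.id, "CAN sample time outside [0, 12] h")
        if not s.doses:
            add("warning", s.id, "no dose events recorded")
        if s.covariates is not None and not 0.0 < s.covariates.hematocrit < 1.0:
            add("error", s.id, "hematocrit outside (0, 1)")
    return findings
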
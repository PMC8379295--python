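"""Core data types and I/O for per-cycle menstrual records.

A cohort is a collection of women, each contributing an ordered series of
menstrual cycles.  For every cycle we know its observed length in whole days,
the woman's age at that cycle, and a vector of non-negative symptom report
counts (how many times e.g. "stomach cramps" was logged during that cycle).
BMI is optional.  The canonical on-disk format is a long CSV with one row per
(woman, cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "CohortValidationError",
    "ConfigurationError",
    "CycleRecord",
    "CycleSeries",
    "Cohort",
    "BmiCategory",
    "BMI_CATEGORIES",
    "classify_bmi",
    "read_cohort",
    "write_cohort",
    "first_sequence_filter",
    "covariate_matrix",
    "PreparedData",
    "prepare_arrays",
    "DEFAULT_PLAUSIBILITY_WINDOW",
    "DEFAULT_SCHEMA",
]

#: Observed range of plausible cycle lengths (days) used for validation.
DEFAULT_PLAUSIBILITY_WINDOW = (18, 43)

#: Default column-name mapping for the long CSV format.
DEFAULT_SCHEMA = {
    "woman_id": "woman_id",
    "cycle_index": "cycle_index",
    "length_days": "length_days",
    "age_years": "age_years",
    "bmi": "bmi",
    "sequence_break": "sequence_break",
}

_RESERVED = set(DEFAULT_SCHEMA)


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class CohortValidationError(ValueError):
    """A row violates a cohort invariant (non-integer length, bad index...)."""


class ConfigurationError(ValueError):
    """An option refers to something that does not exist (e.g. covariate name)."""


@dataclass(frozen=True)
class CycleRecord:
    """One observed menstrual cycle.

    Attributes
    ----------
    woman_id : str
        Opaque identifier of the woman.
    cycle_index : int
        1-based position of the cycle within the woman's series.
    length_days : int
        Observed cycle length in whole days.
    age_years : float
        Age at the cycle, decimal years.
    counts : tuple of int
        Per-cycle symptom report counts, one entry per covariate.
    bmi : float or None
        Body-mass index in kg/m^2, if reported.
    """

    woman_id: str
    cycle_index: int
    length_days: int
    age_years: float
    counts: tuple = ()
    bmi: float | None = None


@dataclass
class CycleSeries:
    """Ordered cycles of a single woman."""

    woman_id: str
    records: list[CycleRecord] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length_days for r in self.records], dtype=float)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_years for r in self.records], dtype=float)

    def validate(self) -> None:
        if not self.records:
            raise CohortValidationError(f"woman {self.woman_id!r}: empty series")
        idx = [r.cycle_index for r in self.records]
        if idx != list(range(1, len(idx) + 1)):
            raise CohortValidationError(
                f"woman {self.woman_id!r}: cycle_index must be 1..J with no gaps, got {idx}"
            )
        for r in self.records:
            if any(c < 0 for c in r.counts):
                raise CohortValidationError(
                    f"woman {self.woman_id!r} cycle {r.cycle_index}: negative covariate count"
                )


@dataclass
class Cohort:
    """A collection of :class:`CycleSeries` sharing one covariate layout."""

    series: list[CycleSeries] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    @property
    def I(self) -> int:  # noqa: E743 - field notation of the model
        return len(self.series)

    @property
    def n_observations(self) -> int:
        return sum(s.n_cycles for s in self.series)

    def woman(self, woman_id: str) -> CycleSeries:
        for s in self.series:
            if s.woman_id == woman_id:
                return s
        raise KeyError(f"unknown woman_id {woman_id!r}")

    def validate(self) -> None:
        ids = [s.woman_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("woman_ids are not unique")
        k = len(self.covariate_names)
        for s in self.series:
            s.validate()
            for r in s.records:
                if len(r.counts) != k:
                    raise CohortValidationError(
                        f"woman {s.woman_id!r}: covariate vector length "
                        f"{len(r.counts)} != {k}"
                    )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per woman/cycle)."""
        rows = []
        for s in self.series:
            for r in s.records:
                row = {
                    "woman_id": r.woman_id,
                    "cycle_index": r.cycle_index,
                    "length_days": r.length_days,
                    "age_years": r.age_years,
                }
                row.update(dict(zip(self.covariate_names, r.counts)))
                if r.bmi is not None:
                    row["bmi"] = r.bmi
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BMI classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BmiCategory:
    """A BMI class with half-open support (lower, upper]."""

    label: str
    lower: float  # exclusive, except the first category which is unbounded below
    upper: float  # inclusive; +inf for the last category

    def contains(self, bmi: float) -> bool:
        return self.lower < bmi <= self.upper


#: Standard eight-class BMI partition; boundaries are lower-exclusive /
#: upper-inclusive, so 25.0 is still "Normal" and 25.0001 is "Overweight".
BMI_CATEGORIES = (
    BmiCategory("Underweight II", 0.0, 15.0),
    BmiCategory("Underweight I", 15.0, 16.0),
    BmiCategory("Underweight", 16.0, 18.5),
    BmiCategory("Normal", 18.5, 25.0),
    BmiCategory("Overweight", 25.0, 30.0),
    BmiCategory("Obese Class I", 30.0, 35.0),
    BmiCategory("Obese Class II", 35.0, 40.0),
    BmiCategory("Obese Class III", 40.0, float("inf")),
)


def classify_bmi(bmi: float) -> BmiCategory:
    """Return the unique BMI category containing ``bmi`` (kg/m^2, > 0)."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi}")
    for cat in BMI_CATEGORIES:
        if cat.contains(bmi):
            return cat
    raise AssertionError("unreachable: categories partition (0, inf)")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    plausibility_window: tuple[int, int] = DEFAULT_PLAUSIBILITY_WINDOW,
    on_implausible: str = "drop",
) -> Cohort:
    """Read a long-format CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path : path-like or buffer
        CSV with a header row; one row per (woman, cycle).
    schema : mapping, optional
        Maps canonical names (``woman_id``, ``cycle_index``, ``length_days``,
        ``age_years``, ``bmi``, ``sequence_break``) to actual column names.
    covariates : sequence of str, optional
        Which columns hold symptom counts.  Defaults to every non-reserved
        column.  Missing cells are imputed as 0 (a symptom that was not
        reported is indistinguishable from one that did not happen); the
        number of imputations is logged.
    plausibility_window : (low, high)
        Inclusive bounds on credible cycle lengths in days.
    on_implausible : {"drop", "keep", "error"}
        What to do with rows outside the window.  Dropping renumbers the
        remaining cycles consecutively.
    """
    if on_implausible not in {"drop", "keep", "error"}:
        raise ConfigurationError(f"on_implausible={on_implausible!r}")
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for canon in ("woman_id", "cycle_index", "length_days", "age_years"):
        col = schema[canon]
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} ({canon}) not found")
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)

    if covariates is None:
        covariates = [c for c in df.columns if c not in _RESERVED]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise SchemaError(f"covariate columns not found: {missing}")
    covariates = list(covariates)

    # integer cycle lengths, with row numbers in the error message
    lengths = pd.to_numeric(df["length_days"], errors="coerce")
    bad = df.index[lengths.isna() | (lengths != np.round(lengths))]
    if len(bad):
        raise CohortValidationError(
            f"non-integer cycle length at CSV row(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    df["length_days"] = lengths.astype(int)

    n_imputed = int(df[covariates].isna().sum().sum()) if covariates else 0
    if n_imputed:
        logger.info("imputed %d missing covariate cells as 0", n_imputed)
        df[covariates] = df[covariates].fillna(0)

    lo, hi = plausibility_window
    outside = (df["length_days"] < lo) | (df["length_days"] > hi)
    if outside.any():
        msg = (
            f"{int(outside.sum())} row(s) outside plausibility window "
            f"[{lo}, {hi}] days"
        )
        if on_implausible == "error":
            raise CohortValidationError(msg)
        logger.warning("%s -> %s", msg, on_implausible)
        if on_implausible == "drop":
            df = df.loc[~outside]

    series: list[CycleSeries] = []
    for wid, grp in df.groupby("woman_id", sort=True):
        grp = grp.sort_values("cycle_index")
        recs = []
        for j, (_, row) in enumerate(grp.iterrows(), start=1):
            bmi = row.get("bmi")
            bmi = float(bmi) if bmi is not None and np.isfinite(bmi) else None
            recs.append(
                CycleRecord(
                    woman_id=str(wid),
                    cycle_index=j,  # renumber consecutively after any drops
                    length_days=int(row["length_days"]),
                    age_years=float(row["age_years"]),
                    counts=tuple(int(row[c]) for c in covariates),
                    bmi=bmi,
                )
            )
        series.append(CycleSeries(str(wid), recs))
    cohort = Cohort(series=series, covariate_names=covariates)

    if "sequence_break" in df.columns:
        breaks = {
            (str(w), int(j))
            for w, j, b in zip(df["woman_id"], df["cycle_index"], df["sequence_break"])
            if bool(b) and np.isfinite(float(b))
        }
        cohort = first_sequence_filter(cohort, breaks=breaks)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to the long CSV format (inverse of read_cohort)."""
    cohort.to_frame().to_csv(path, index=False)


def first_sequence_filter(
    cohort: Cohort, breaks: Iterable[tuple[str, int]] | None = None
) -> Cohort:
    """Keep only each woman's first contiguous sequence of cycles.

    A "break" marks the first cycle *after* a reporting gap or dropout; all
    cycles from the break onward are discarded and the survivors renumbered
    from 1.  Women contributing more than one sequence would otherwise bias
    the dynamics, since the reason for the gap is unknown.  With no break
    markers this is the identity.
    """
    if not breaks:
        return cohort
    breaks = set(breaks)
    out = []
    for s in cohort.series:
        cut = s.n_cycles + 1
        for wid, j in breaks:
            if wid == s.woman_id:
                cut = min(cut, j)
        kept = [r for r in s.records if r.cycle_index < cut]
        if not kept and s.records:
            # break flagged at cycle 1: retain that single record
            kept = s.records[:1]
        recs = [
            CycleRecord(r.woman_id, j, r.length_days, r.age_years, r.counts, r.bmi)
            for j, r in enumerate(kept, start=1)
        ]
        out.append(CycleSeries(s.woman_id, recs))
    return Cohort(series=out, covariate_names=list(cohort.covariate_names))


def covariate_matrix(
    series: CycleSeries, selected: Sequence[str], covariate_names: Sequence[str]
) -> np.ndarray:
    """Per-cycle count matrix (J_i x K') in the order of ``selected``.

    Entry (j, k) is the number of times symptom ``selected[k]`` was reported
    during cycle j; a symptom logged t times contributes a count of t, so the
    linear predictor term is alpha_k * t.
    """
    name_to_pos = {n: i for i, n in enumerate(covariate_names)}
    unknown = [n for n in selected if n not in name_to_pos]
    if unknown:
        raise ConfigurationError(f"unknown covariate name(s): {unknown}")
    cols = [name_to_pos[n] for n in selected]
    mat = np.zeros((series.n_cycles, len(cols)), dtype=float)
    for j, r in enumerate(series.records):
        for k, c in enumerate(cols):
            mat[j, k] = r.counts[c]
    return mat


# ---------------------------------------------------------------------------
# Dense array view used by the numerical core
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    """Padded rectangular view of a cohort.

    Arrays are (I, Jmax) with ``mask`` flagging real cells; covariate counts
    are (I, Jmax, K).  Cycles are contiguous from column 0.
    """

    y: np.ndarray
    mask: np.ndarray
    ages: np.ndarray
    counts: np.ndarray
    woman_ids: list[str]
    covariate_names: list[str]

    @property
    def n_women(self) -> int:
        return self.y.shape[0]

    @property
    def j_max(self) -> int:
        return self.y.shape[1]

    @property
    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def index_of(self, woman_id: str) -> int:
        try:
            return self.woman_ids.index(woman_id)
        except ValueError:
            raise KeyError(f"unknown woman_id {woman_id!r}") from None


def prepare_arrays(cohort: Cohort, covariates: Sequence[str] | None = None) -> PreparedData:
    """Convert a cohort to the padded array layout used by the samplers."""
    if covariates is None:
        covariates = list(cohort.covariate_names)
    jmax = max((s.n_cycles for s in cohort.series), default=0)
    I = cohort.I
    K = len(covariates)
    y = np.zeros((I, jmax))
    mask = np.zeros((I, jmax), dtype=bool)
    ages = np.zeros((I, jmax))
    counts = np.zeros((I, jmax, K))
    ids = []
    for i, s in enumerate(cohort.series):
        ids.append(s.woman_id)
        J = s.n_cycles
        y[i, :J] = s.lengths
        ages[i, :J] = s.ages
        mask[i, :J] = True
        if K:
            counts[i, :J, :] = covariate_matrix(s, covariates, cohort.covariate_names)
    return PreparedData(y, mask, ages, counts, ids, list(covariates))
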
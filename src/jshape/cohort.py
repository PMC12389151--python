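"""Longitudinal cohort data model: scoring, exposure classification, exclusions, I/O.

The package works on long-format tables with one row per participant-wave.
Wave 0 is baseline; waves are annual. A participant's observed waves form a
contiguous prefix 0..k (monotone dropout); a wave that was administered but
whose depression scale is missing is treated as a censored outcome wave and
handled downstream by inverse-probability-of-censoring weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four exposure categories, in display order. ``moderate`` is the
#: reference level of every contrast in the package.
CATEGORIES = ("abstainer", "occasional", "moderate", "above_guideline")
REFERENCE = "moderate"

#: Sex-specific weekly standard-drink limits for the "moderate" category.
WEEKLY_LIMIT = {"female": 7.0, "male": 14.0}

#: 1-based positions of the two positive-mood items of the 10-item CES-D
#: short form ("hopeful about the future", "happy"), reverse-coded.
DEFAULT_REVERSE_POSITIONS = (5, 8)

MANDATORY_COLUMNS = ("participant_id", "wave")


class CohortValidationError(ValueError):
    """Raised when a table violates the cohort contract."""


@dataclass
class CohortTable:
    """Long-format cohort: one row per observed participant-wave.

    Parameters
    ----------
    data
        Long table. Mandatory columns: ``participant_id``, ``wave``.
        Typical columns: ``days_per_week``, ``drinks_per_day``,
        ``heavy_episodic``, ``alcohol_category``, ``former_drinker``,
        ``cesd_score``, ``depressed``, ``censored``, plus covariates.
    baseline_covariates
        Covariate columns measured once, at wave 0 (carried on every row).
    time_updated_covariates
        Covariate columns that are re-measured at every wave.
    sex_column
        Binary column coding sex; 1 = female, 0 = male.
    """

    data: pd.DataFrame
    baseline_covariates: list[str] = field(default_factory=list)
    time_updated_covariates: list[str] = field(default_factory=list)
    sex_column: str = "female"

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    @property
    def n_waves(self) -> int:
        return int(self.data["wave"].max()) + 1

    @property
    def covariates(self) -> list[str]:
        return list(self.baseline_covariates) + list(self.time_updated_covariates)

    def baseline(self) -> pd.DataFrame:
        """Rows at wave 0."""
        return self.data.loc[self.data["wave"] == 0]

    def validate(self) -> "CohortTable":
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"missing mandatory column {col!r}")
        dup = df.duplicated(subset=["participant_id", "wave"])
        if dup.any():
            row = df.index[dup][0]
            raise CohortValidationError(f"duplicate (participant_id, wave) at row {row}")
        # waves must be a contiguous prefix 0..k per participant
        by = df.groupby("participant_id")["wave"]
        bad = by.apply(lambda w: not np.array_equal(np.sort(w.to_numpy()), np.arange(len(w))))
        if bad.any():
            pid = bad.index[bad.argmax()]
            raise CohortValidationError(
                f"participant {pid!r}: observed waves are not a contiguous prefix 0..k"
            )
        if "censored" in df.columns:
            base = df.loc[df["wave"] == 0, "censored"]
            if base.astype(bool).any():
                raise CohortValidationError("wave 0 must not be censored")
        return self

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.data.copy(),
            list(self.baseline_covariates),
            list(self.time_updated_covariates),
            self.sex_column,
        )


@dataclass
class ExclusionReport:
    """Accounting of cohort exclusion rules, applied in order."""

    n_input: int
    removed: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.removed.values()) != self.n_input:
            raise AssertionError("exclusion accounting does not balance")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_retained": self.n_retained,
        }


def score_cesd10(
    items: Sequence[int],
    reverse_positions: Iterable[int] = DEFAULT_REVERSE_POSITIONS,
) -> int:
    """Total score of the 10-item CES-D short form.

    Items are coded 0-3 (frequency of each symptom in the past week); the
    positive-mood items at ``reverse_positions`` (1-based) are reverse-coded
    as ``3 - value`` before summing. The total ranges 0-30.
    """
    items = list(items)
    if len(items) != 10:
        raise ValueError(f"expected 10 items, got {len(items)}")
    reverse = set(reverse_positions)
    if not reverse <= set(range(1, 11)):
        raise ValueError(f"reverse positions must be within 1..10, got {sorted(reverse)}")
    total = 0
    for pos, value in enumerate(items, start=1):
        if value not in (0, 1, 2, 3):
            raise ValueError(f"item {pos} out of range 0-3: {value!r}")
        total += 3 - value if pos in reverse else value
    return total


def classify_depression(score: int, cutoff: int = 8) -> bool:
    """Probable depression: CES-D-10 total at or above ``cutoff``.

    The primary threshold is 8; 10 is the conventional stricter alternative.
    Other cutoffs are accepted but unusual.
    """
    if not 0 <= score <= 30:
        raise ValueError(f"CES-D-10 score out of range 0-30: {score}")
    return score >= cutoff


def classify_alcohol(
    days_per_week: float,
    drinks_per_day: float,
    heavy_episodic: bool,
    sex: str,
) -> str:
    """Assign one of the four alcohol-consumption categories.

    Rules (``weekly = days_per_week * drinks_per_day``; limit 7 std
    drinks/week for women, 14 for men):

    - ``abstainer``: no consumption at all;
    - ``occasional``: drinks on fewer than 1 day/week, no heavy episodes;
    - ``moderate``: >= 1 day/week, weekly total within the sex-specific
      limit, no heavy episodes;
    - ``above_guideline``: weekly total strictly above the limit at >= 1
      day/week, and/or any heavy episodic drinking (>= 5 drinks on one
      occasion for men, >= 4 for women) with nonzero consumption.

    A weekly total exactly at the limit counts as moderate, keeping the
    rule a partition with moderate as the reference.
    """
    if days_per_week < 0 or days_per_week > 7:
        raise ValueError(f"days_per_week out of range 0-7: {days_per_week}")
    if drinks_per_day < 0:
        raise ValueError(f"drinks_per_day negative: {drinks_per_day}")
    if sex not in WEEKLY_LIMIT:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    zero = days_per_week == 0 and drinks_per_day == 0
    if days_per_week == 0 and drinks_per_day > 0:
        raise ValueError(
            "inconsistent record: drinks_per_day > 0 with days_per_week == 0"
        )
    if zero:
        if heavy_episodic:
            raise ValueError("inconsistent record: heavy episodic drinking with zero consumption")
        return "abstainer"
    if heavy_episodic:
        return "above_guideline"
    if days_per_week < 1:
        return "occasional"
    weekly = days_per_week * drinks_per_day
    return "moderate" if weekly <= WEEKLY_LIMIT[sex] else "above_guideline"


def classify_alcohol_frame(df: pd.DataFrame, female_col: str = "female") -> pd.Series:
    """Vectorised :func:`classify_alcohol` over a long table."""
    sex = np.where(df[female_col].astype(bool), "female", "male")
    out = [
        classify_alcohol(d, k, bool(h), s)
        for d, k, h, s in zip(df["days_per_week"], df["drinks_per_day"], df["heavy_episodic"], sex)
    ]
    return pd.Series(pd.Categorical(out, categories=list(CATEGORIES)), index=df.index)


# ---------------------------------------------------------------------------
# Exclusion rules

def _rule_missing_baseline_outcome(base: pd.DataFrame, **_: object) -> pd.Series:
    return base["cesd_score"].isna()


def _rule_baseline_psychotropic_use(base: pd.DataFrame, column: str = "psychotropic_use", **_: object) -> pd.Series:
    if column not in base.columns:
        raise KeyError(f"exclusion rule needs column {column!r}")
    return base[column].astype(bool)


def _rule_former_drinker(base: pd.DataFrame, **_: object) -> pd.Series:
    return base["former_drinker"].astype(bool)


def _rule_baseline_depressed(base: pd.DataFrame, cutoff: int = 8, **_: object) -> pd.Series:
    return base["cesd_score"] >= cutoff


_EXCLUSION_RULES = {
    "missing_baseline_outcome": _rule_missing_baseline_outcome,
    "baseline_psychotropic_use": _rule_baseline_psychotropic_use,
    "former_drinker": _rule_former_drinker,
    "baseline_depressed": _rule_baseline_depressed,
}


def apply_exclusions(
    cohort: CohortTable,
    rules: Sequence[str | tuple[str, Mapping]],
) -> tuple[CohortTable, ExclusionReport]:
    """Drop participants per an ordered list of exclusion rules.

    Each rule is a name (``missing_baseline_outcome``,
    ``baseline_psychotropic_use``, ``former_drinker``,
    ``baseline_depressed``) or a ``(name, kwargs)`` pair, e.g.
    ``("baseline_depressed", {"cutoff": 10})``. Rules are evaluated on
    baseline rows against the then-current participant set, so per-rule
    counts depend on order while the final retained set does not.
    """
    df = cohort.data
    removed: dict[str, int] = {}
    n_input = df["participant_id"].nunique()
    for rule in rules:
        name, kwargs = (rule, {}) if isinstance(rule, str) else (rule[0], dict(rule[1]))
        if name not in _EXCLUSION_RULES:
            raise KeyError(
                f"unknown exclusion rule {name!r}; known: {sorted(_EXCLUSION_RULES)}"
            )
        base = df.loc[df["wave"] == 0]
        mask = _EXCLUSION_RULES[name](base, **kwargs)
        drop_ids = set(base.loc[mask.fillna(False).astype(bool), "participant_id"])
        removed[name] = len(drop_ids)
        df = df.loc[~df["participant_id"].isin(drop_ids)]
    report = ExclusionReport(n_input, removed, df["participant_id"].nunique())
    out = cohort.copy()
    out.data = df.reset_index(drop=True)
    return out, report


def lag_exposure(cohort: CohortTable, lag_waves: int = 1) -> pd.DataFrame:
    """Pair exposure at wave t with the outcome at wave t + lag.

    Returns one analysis row per (participant, exposure wave) with the
    exposure category and time-updated covariates measured at ``wave``, the
    outcome measured at ``outcome_wave = wave + lag_waves``, and an
    ``outcome_censored`` flag when the outcome wave was not observed (such
    rows are kept so censoring-weight bookkeeping can see them; they never
    enter an outcome fit unweighted). The lag enforces temporal ordering of
    exposure before outcome.
    """
    if lag_waves < 1:
        raise ValueError("lag_waves must be >= 1")
    df = cohort.data
    if cohort.n_waves < lag_waves + 1:
        import warnings

        warnings.warn("cohort has too few waves for the requested lag; empty table")
        return df.iloc[:0].assign(outcome_wave=[], outcome_censored=[])

    keep = ["participant_id", "wave", "alcohol_category"] + [
        c for c in cohort.covariates if c in df.columns
    ]
    if "former_drinker" in df.columns:
        keep.append("former_drinker")
    left = df[keep].copy()
    left["outcome_wave"] = left["wave"] + lag_waves
    outcome_cols = ["participant_id", "wave", "cesd_score"]
    if "depressed" in df.columns:
        outcome_cols.append("depressed")
    right = df[outcome_cols].rename(
        columns={"wave": "outcome_wave", "cesd_score": "outcome_cesd_score",
                 "depressed": "outcome_depressed"}
    )
    merged = left.merge(right, on=["participant_id", "outcome_wave"], how="left")
    # drop exposure waves whose outcome wave lies beyond the study horizon
    merged = merged.loc[merged["outcome_wave"] <= cohort.n_waves - 1].copy()
    merged["outcome_censored"] = merged["outcome_cesd_score"].isna()
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O: CSV/TSV with a JSON sidecar describing covariate roles

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_cohort(cohort: CohortTable, path: str | Path, dialect: str = "csv") -> None:
    """Write the long table plus a JSON sidecar of covariate roles."""
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    cohort.data.to_csv(path, sep=sep, index=False)
    meta = {
        "baseline_covariates": cohort.baseline_covariates,
        "time_updated_covariates": cohort.time_updated_covariates,
        "sex_column": cohort.sex_column,
        "sex_coding": {"1": "female", "0": "male"},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_cohort(path: str | Path, dialect: str = "csv") -> CohortTable:
    """Read a cohort written by :func:`write_cohort`; round-trip lossless."""
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"{path}: missing mandatory column {col!r}")
    for col in ("heavy_episodic", "former_drinker", "censored", "depressed"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype("boolean").astype(object).where(df[col].notna())
            # plain bool when no missing values, nullable otherwise
            if df[col].notna().all():
                df[col] = df[col].astype(bool)
    meta_path = _sidecar_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"baseline_covariates": [], "time_updated_covariates": [], "sex_column": "female"}
    table = CohortTable(
        df,
        baseline_covariates=list(meta.get("baseline_covariates", [])),
        time_updated_covariates=list(meta.get("time_updated_covariates", [])),
        sex_column=meta.get("sex_column", "female"),
    )
    return table.validate()
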
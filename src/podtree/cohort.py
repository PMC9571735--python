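"""Patient cohort data model: cue dictionary, CSV I/O, imputation, half-splits.

The cohort is a flat patient-by-cue table with a binary postoperative-delirium
(POD) outcome.  Cues are the pre-operative patient attributes recorded at
admission (age, ASA physical status, Charlson Comorbidity Index, frailty
phenotype, ...) plus two intraoperative ones (duration of anesthesia and
premedication).  All cues arrive pre-coded on their clinical scales; this
module never computes clinical scores.

Missing values are carried as ``NaN`` internally; in CSV files an empty cell
or ``"."`` marks a missing value.  Imputation replaces missing cells using
whole-sample statistics computed *before* any train/test splitting, which is
deliberate: the study protocol this package implements prepared the dataset
once, prior to the model comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CueSpec",
    "CohortTable",
    "SplitPair",
    "OUTCOME",
    "NUMERIC",
    "ORDINAL",
    "BINARY",
    "PREOPERATIVE",
    "INTRAOPERATIVE",
    "default_cue_dict",
    "preoperative_cue_names",
    "read_cohort",
    "write_cohort",
    "impute_missing",
    "split_half",
]

#: name of the outcome column in data frames and CSV files (1 = POD)
OUTCOME = "pod"

#: strings treated as missing markers when reading CSV
NA_VALUES = ("", ".")

NUMERIC = "numeric"
ORDINAL = "ordinal"
BINARY = "binary"
PREOPERATIVE = "preoperative"
INTRAOPERATIVE = "intraoperative"

_KINDS = (NUMERIC, ORDINAL, BINARY)
_ROLES = (PREOPERATIVE, INTRAOPERATIVE)
_IMPUTE_RULES = ("auto", "median", "mode", "constant", "none")


@dataclass(frozen=True)
class CueSpec:
    """Description of one cue: measurement kind, perioperative role, imputation rule.

    Parameters
    ----------
    name : str
        Column name of the cue.
    kind : {"numeric", "ordinal", "binary"}
        Measurement kind.  Ordinal and binary cues are thresholded on their
        integer coding, so they must carry explicit ordered ``levels``.
    role : {"preoperative", "intraoperative"}
        Whether the cue is available before surgery or only afterwards.
    impute : {"auto", "median", "mode", "constant", "none"}
        Imputation rule.  ``"auto"`` resolves to the sample median for numeric
        cues and the sample mode for ordinal/binary cues.  ``"constant"``
        requires ``impute_value``.
    impute_value : float, optional
        Replacement value for the ``"constant"`` rule.
    levels : tuple of float, optional
        Ordered legal values (required for ordinal cues; binary cues default
        to ``(0, 1)``).
    integer : bool
        Whether the cue lives on an integer coding grid.  Medians of
        even-count samples are rounded half-up back onto the grid for such
        cues.  Always true for ordinal/binary cues.
    """

    name: str
    kind: str
    role: str = PREOPERATIVE
    impute: str = "auto"
    impute_value: float | None = None
    levels: tuple[float, ...] | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown cue kind {self.kind!r} for cue {self.name!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown cue role {self.role!r} for cue {self.name!r}")
        if self.impute not in _IMPUTE_RULES:
            raise ValueError(f"unknown imputation rule {self.impute!r} for cue {self.name!r}")
        if self.impute == "constant" and self.impute_value is None:
            raise ValueError(f"cue {self.name!r}: constant imputation needs impute_value")
        if self.kind == BINARY and self.levels is None:
            object.__setattr__(self, "levels", (0.0, 1.0))
        if self.kind == ORDINAL and self.levels is None:
            raise ValueError(f"ordinal cue {self.name!r} needs an explicit ordered coding")
        if self.levels is not None and list(self.levels) != sorted(self.levels):
            raise ValueError(f"cue {self.name!r}: levels must be ordered")
        if self.kind in (ORDINAL, BINARY):
            object.__setattr__(self, "integer", True)

    @property
    def effective_impute(self) -> str:
        if self.impute == "auto":
            return "median" if self.kind == NUMERIC else "mode"
        return self.impute


def _cue(name, kind, *, role=PREOPERATIVE, impute="auto", value=None, levels=None, integer=False):
    return CueSpec(name, kind, role=role, impute=impute, impute_value=value,
                   levels=levels, integer=integer)


# Default cue dictionary.  Ordinal codings:
#   surgery_site: 1 = intracranial, 2 = intrathoracic/intra-abdominal/pelvic,
#                 3 = peripheral
#   frailty:      0 = robust, 1 = pre-frail, 2 = frail
#   asa_ps:       integer ASA physical-status class 1-4
#   mna:          0 (worst) .. 3 (no impairment)
# Imputation follows the study protocol: median for ISCED, GDS, pack years and
# duration of anesthesia; constant 0 (no impairment / not given) for the four
# named comorbidities, cognitive impairment, ADL, IADL and premedication;
# constant 3 for MNA; sample median/mode otherwise.
_DEFAULT_CUES: tuple[CueSpec, ...] = (
    _cue("age", NUMERIC, integer=True),
    _cue("sex", BINARY),
    _cue("height", NUMERIC),
    _cue("bmi", NUMERIC),
    _cue("asa_ps", ORDINAL, levels=(1, 2, 3, 4)),
    _cue("cci", NUMERIC, integer=True),
    _cue("hypertension", BINARY, impute="constant", value=0),
    _cue("coronary_artery_disease", BINARY, impute="constant", value=0),
    _cue("diabetes", BINARY, impute="constant", value=0),
    _cue("stroke_tia", BINARY, impute="constant", value=0),
    _cue("isced", ORDINAL, impute="median", levels=(0, 1, 2, 3, 4, 5, 6)),
    _cue("mmse", NUMERIC, integer=True),
    _cue("cognitive_impairment", BINARY, impute="constant", value=0),
    _cue("adl_impaired", BINARY, impute="constant", value=0),
    _cue("iadl_impaired", BINARY, impute="constant", value=0),
    _cue("mna", ORDINAL, impute="constant", value=3, levels=(0, 1, 2, 3)),
    _cue("frailty", ORDINAL, levels=(0, 1, 2)),
    _cue("gds", NUMERIC, impute="median", integer=True),
    _cue("benzodiazepines", BINARY),
    _cue("hazardous_alcohol", BINARY),
    _cue("smoker", BINARY),
    _cue("pack_years", NUMERIC, impute="median"),
    _cue("surgery_site", ORDINAL, levels=(1, 2, 3)),
    _cue("anesthesia_duration", NUMERIC, role=INTRAOPERATIVE, impute="median", integer=True),
    _cue("premedication", BINARY, role=INTRAOPERATIVE, impute="constant", value=0),
)


def default_cue_dict(include_intraoperative: bool = True) -> list[CueSpec]:
    """Return the default cue dictionary (23 pre-operative cues, 25 in total)."""
    if include_intraoperative:
        return list(_DEFAULT_CUES)
    return [c for c in _DEFAULT_CUES if c.role == PREOPERATIVE]


def preoperative_cue_names() -> list[str]:
    return [c.name for c in _DEFAULT_CUES if c.role == PREOPERATIVE]


class CohortTable:
    """Patient records x cue columns plus an optional binary POD outcome.

    Wraps a :class:`pandas.DataFrame` whose columns are the cue names from the
    cue dictionary plus, when present, the outcome column ``"pod"``.  The
    outcome, when present, must be strictly binary with no missing values;
    cue cells may be ``NaN`` (explicit missing marker) until imputation.
    """

    def __init__(self, data: pd.DataFrame, cues: Sequence[CueSpec] | None = None,
                 *, copy: bool = True, validate: bool = True) -> None:
        if cues is None:
            known = {c.name: c for c in _DEFAULT_CUES}
            cues = [known[c] if c in known else _cue(c, NUMERIC)
                    for c in data.columns if c != OUTCOME]
        self.cues: list[CueSpec] = list(cues)
        cols = [c.name for c in self.cues]
        if OUTCOME in data.columns:
            cols = cols + [OUTCOME]
        data = data.loc[:, cols]
        self.data: pd.DataFrame = data.copy() if copy else data
        self.data.reset_index(drop=True, inplace=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        for cue in self.cues:
            if cue.name not in self.data.columns:
                raise ValueError(f"cohort is missing cue column {cue.name!r}")
        if OUTCOME in self.data.columns:
            y = self.data[OUTCOME]
            if y.isna().any():
                raise ValueError("outcome column contains missing values")
            bad = set(np.unique(y)) - {0, 1}
            if bad:
                raise ValueError(f"outcome must be binary 0/1, found values {sorted(bad)}")
            self.data[OUTCOME] = y.astype(np.int64)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return self.n

    @property
    def cue_names(self) -> list[str]:
        return [c.name for c in self.cues]

    @property
    def has_outcome(self) -> bool:
        return OUTCOME in self.data.columns

    @property
    def outcome(self) -> np.ndarray:
        self.require_outcome()
        return self.data[OUTCOME].to_numpy()

    def require_outcome(self) -> None:
        if not self.has_outcome:
            raise ValueError("cohort has no outcome column")

    @property
    def cue_frame(self) -> pd.DataFrame:
        return self.data[self.cue_names]

    def spec(self, name: str) -> CueSpec:
        for c in self.cues:
            if c.name == name:
                return c
        raise KeyError(name)

    def n_missing(self) -> int:
        return int(self.cue_frame.isna().to_numpy().sum())

    def copy(self) -> "CohortTable":
        return CohortTable(self.data, self.cues, copy=True, validate=False)

    def take(self, indices: Iterable[int]) -> "CohortTable":
        idx = np.asarray(list(indices), dtype=np.int64)
        return CohortTable(self.data.iloc[idx], self.cues, copy=True, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        out = "with" if self.has_outcome else "without"
        return f"<CohortTable n={self.n} cues={len(self.cues)} {out} outcome>"


@dataclass(frozen=True)
class SplitPair:
    """An equal-size random train/test partition of a parent cohort."""

    train: CohortTable
    test: CohortTable
    seed: int


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, cues: Sequence[CueSpec] | None = None) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Empty cells and ``"."`` are missing markers; any other unparseable cell
    also becomes missing.  Columns not in the cue dictionary are dropped with
    a warning; a missing or non-binary outcome column is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=False,
                     skipinitialspace=True)
    if OUTCOME not in df.columns:
        raise ValueError(f"{path}: cohort CSV has no {OUTCOME!r} outcome column")
    if cues is None:
        known = {c.name: c for c in _DEFAULT_CUES}
        cues = [known.get(c, _cue(c, NUMERIC)) for c in df.columns if c != OUTCOME]
    wanted = {c.name for c in cues} | {OUTCOME}
    unknown = [c for c in df.columns if c not in wanted]
    if unknown:
        warnings.warn(f"{path}: dropping unknown columns {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    for cue in cues:
        if cue.name not in df.columns:
            raise ValueError(f"{path}: cohort CSV is missing cue column {cue.name!r}")
        df[cue.name] = pd.to_numeric(df[cue.name], errors="coerce")
    y = pd.to_numeric(df[OUTCOME], errors="coerce")
    if y.isna().any() or not set(np.unique(y.dropna())) <= {0, 1}:
        raise ValueError(f"{path}: outcome column must be strictly binary 0/1")
    df[OUTCOME] = y.astype(np.int64)
    return CohortTable(df, cues, copy=False)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV, empty cells marking missing values."""
    cols = table.cue_names + ([OUTCOME] if table.has_outcome else [])
    table.data[cols].to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def _impute_value(col: pd.Series, cue: CueSpec) -> float:
    rule = cue.effective_impute
    if rule == "constant":
        return float(cue.impute_value)
    observed = col.dropna()
    if observed.empty:
        raise ValueError(f"cue {cue.name!r}: all values missing, cannot impute by {rule}")
    if rule == "median":
        m = float(observed.median())
        if cue.integer:
            m = _round_half_up(m)
            if cue.levels is not None:
                # snap onto the coding grid (nearest legal level, ties upward)
                lv = np.asarray(cue.levels, dtype=float)
                d = np.abs(lv - m)
                m = float(lv[d == d.min()].max())
        return m
    if rule == "mode":
        counts = observed.value_counts()
        top = counts[counts == counts.max()]
        return float(min(top.index))  # ties: smallest value wins
    raise AssertionError(rule)


def impute_missing(table: CohortTable) -> CohortTable:
    """Replace every missing cue cell using whole-sample statistics.

    Observed cells, the outcome and the row count are never altered, and the
    operation is idempotent.  Cues with rule ``"none"`` are left untouched.
    """
    if table.n == 0:
        raise ValueError("cannot impute an empty cohort")
    df = table.data.copy()
    for cue in table.cues:
        col = df[cue.name]
        if not col.isna().any() or cue.effective_impute == "none":
            continue
        df[cue.name] = col.fillna(_impute_value(col, cue))
    return CohortTable(df, table.cues, copy=False, validate=False)


# ---------------------------------------------------------------------------
# Train/test half-splits
# ---------------------------------------------------------------------------

def split_half(table: CohortTable, seed: int) -> SplitPair:
    """Uniform random partition into halves of size ceil(n/2) and floor(n/2).

    Deterministic given ``seed``; the two halves are disjoint and exhaust the
    parent table.
    """
    n = table.n
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = -(-n // 2)  # ceil
    train_idx = np.sort(perm[:k])
    test_idx = np.sort(perm[k:])
    return SplitPair(train=table.take(train_idx), test=table.take(test_idx), seed=seed)
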
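"""Repeated paired-split model comparison.

The validation protocol: the imputed cohort is repeatedly split at random
into equal train/test halves; every model is fitted on the training half and
scored on both halves of the *same* split, so that performance differences
are within-split.  Cheap models run on all splits; models flagged ``slow``
(the dfan tree builder in the reference analysis, which ran 1000 of the
10,000 trials) are restricted to the first ``n_trials_slow`` splits.

Per-trial split seeds derive from the master seed by a counter, so "the first
1000 splits" is well defined and any single trial is reproducible in
isolation.  Aggregation reports per-model, per-phase means and standard
errors of sensitivity, specificity and balanced accuracy, plus pairwise win
rates (fraction of shared trials in which one model's test balanced accuracy
strictly exceeds another's; exact ties credit neither model).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, SplitPair, split_half
from .fft import FastFrugalTreeModel
from .metrics import PerfStats
from .reference import BaseRateLogitModel, WeightedTreeModel

__all__ = [
    "ModelSpec",
    "TrialRecord",
    "ComparisonResult",
    "default_model_suite",
    "trial_seed",
    "split_fingerprint",
    "run_comparison",
    "aggregate",
    "win_rate",
]

PHASES = ("train", "test")
_METRICS = ("sens", "spec", "bacc")


@dataclass(frozen=True)
class ModelSpec:
    """A named model constructor for the harness.

    ``build(train)`` must return a fitted object exposing
    ``evaluate(table) -> PerfStats``.
    """

    name: str
    build: Callable[[CohortTable], object]
    slow: bool = False


def default_model_suite(weight: float = 0.5) -> list[ModelSpec]:
    """The four compared models: FFTi, FFTd (slow), UDT, LogReg."""
    return [
        ModelSpec("FFTi", lambda t: FastFrugalTreeModel(t, "ifan", weight=weight).fit()),
        ModelSpec("FFTd", lambda t: FastFrugalTreeModel(t, "dfan", weight=weight).fit(),
                  slow=True),
        ModelSpec("UDT", lambda t: WeightedTreeModel(t).fit()),
        ModelSpec("LogReg", lambda t: BaseRateLogitModel(t).fit()),
    ]


def trial_seed(master_seed: int, trial: int) -> int:
    """Counter-derived per-trial split seed (stable across runs and machines)."""
    state = np.random.SeedSequence([int(master_seed), int(trial)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def split_fingerprint(pair: SplitPair) -> str:
    """Digest of the exact train/test membership of a split."""
    h = hashlib.sha1()
    h.update(pair.train.data.index.size.to_bytes(8, "little"))
    h.update(np.ascontiguousarray(pair.train.outcome).tobytes())
    h.update(b"|")
    h.update(np.ascontiguousarray(pair.test.outcome).tobytes())
    h.update(pair.train.cue_frame.to_numpy(dtype=float).tobytes())
    h.update(pair.test.cue_frame.to_numpy(dtype=float).tobytes())
    return h.hexdigest()


@dataclass
class TrialRecord:
    """Per-trial results: one shared split, per-model train/test statistics."""

    trial_id: int
    seed: int
    fingerprint: str
    perf: dict[str, dict[str, PerfStats]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


class ComparisonResult:
    """All trials of a comparison run plus aggregation helpers."""

    def __init__(self, trials: list[TrialRecord], model_names: list[str],
                 n_trials_fast: int, n_trials_slow: int, master_seed: int) -> None:
        self.trials = trials
        self.model_names = model_names
        self.n_trials_fast = n_trials_fast
        self.n_trials_slow = n_trials_slow
        self.master_seed = master_seed

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            for model, phases in t.perf.items():
                for phase, p in phases.items():
                    rows.append({"trial_id": t.trial_id, "model": model,
                                 "phase": phase, "sens": p.sens, "spec": p.spec,
                                 "bacc": p.bacc})
        return pd.DataFrame(rows, columns=["trial_id", "model", "phase",
                                           "sens", "spec", "bacc"])

    def test_bacc(self, model: str) -> pd.Series:
        vals = {t.trial_id: t.perf[model]["test"].bacc
                for t in self.trials if model in t.perf}
        return pd.Series(vals, name=model)

    def aggregate(self) -> pd.DataFrame:
        return aggregate(self)

    def win_matrix(self) -> pd.DataFrame:
        m = pd.DataFrame(0.0, index=self.model_names, columns=self.model_names)
        for a in self.model_names:
            for b in self.model_names:
                if a != b:
                    m.loc[a, b] = win_rate(self, a, b)
        return m


def run_comparison(table: CohortTable, models: Sequence[ModelSpec] | None = None,
                   n_trials_fast: int = 10000, n_trials_slow: int = 1000,
                   master_seed: int = 0, progress: bool = False) -> ComparisonResult:
    """Run the repeated paired-split comparison.

    The cohort must be imputed.  Every model in a trial sees the byte-identical
    train/test partition.  A model failing on a single trial is recorded and
    skipped; failing on more than 1% of its trials aborts with diagnostics.
    """
    if table.n_missing():
        raise ValueError("cohort contains missing values; impute before comparing")
    if models is None:
        models = default_model_suite()
    if n_trials_slow > n_trials_fast:
        raise ValueError("n_trials_slow must not exceed n_trials_fast")
    trials: list[TrialRecord] = []
    attempted = {m.name: 0 for m in models}
    failed = {m.name: 0 for m in models}
    for t in range(n_trials_fast):
        seed = trial_seed(master_seed, t)
        pair = split_half(table, seed)
        record = TrialRecord(trial_id=t, seed=seed,
                             fingerprint=split_fingerprint(pair))
        for spec in models:
            if spec.slow and t >= n_trials_slow:
                continue
            attempted[spec.name] += 1
            try:
                fitted = spec.build(pair.train)
                record.perf[spec.name] = {
                    "train": fitted.evaluate(pair.train),
                    "test": fitted.evaluate(pair.test),
                }
            except Exception as exc:  # noqa: BLE001 - recorded per trial
                failed[spec.name] += 1
                record.failures[spec.name] = f"{type(exc).__name__}: {exc}"
        trials.append(record)
        if progress and (t + 1) % 50 == 0:
            print(f"trial {t + 1}/{n_trials_fast}")
    for spec in models:
        if attempted[spec.name] and failed[spec.name] > 0.01 * attempted[spec.name]:
            examples = [t.failures[spec.name] for t in trials
                        if spec.name in t.failures][:5]
            raise RuntimeError(
                f"model {spec.name!r} failed on {failed[spec.name]} of "
                f"{attempted[spec.name]} trials: {examples}")
    return ComparisonResult(trials, [m.name for m in models],
                            n_trials_fast, n_trials_slow, master_seed)


def aggregate(result: ComparisonResult) -> pd.DataFrame:
    """Per-model, per-phase mean and standard error of sens/spec/bacc."""
    rows = []
    for model in result.model_names:
        values = {phase: {m: [] for m in _METRICS} for phase in PHASES}
        for t in result.trials:
            if model not in t.perf:
                continue
            for phase in PHASES:
                p = t.perf[model][phase]
                for m in _METRICS:
                    values[phase][m].append(getattr(p, m))
        for phase in PHASES:
            k = len(values[phase]["bacc"])
            if k < 2:
                raise ValueError(f"model {model!r} has fewer than 2 trials")
            row = {"model": model, "phase": phase, "n_trials": k}
            for m in _METRICS:
                arr = np.asarray(values[phase][m])
                row[f"{m}_mean"] = arr.mean()
                row[f"{m}_se"] = arr.std(ddof=1) / np.sqrt(k)
            rows.append(row)
    return pd.DataFrame(rows).set_index(["model", "phase"])


def win_rate(result: ComparisonResult, a: str, b: str) -> float:
    """Fraction of shared trials where test bacc(a) strictly exceeds test bacc(b)."""
    sa = result.test_bacc(a)
    sb = result.test_bacc(b)
    common = sa.index.intersection(sb.index)
    if len(common) == 0:
        raise ValueError(f"models {a!r} and {b!r} share no trials")
    return float((sa.loc[common] > sb.loc[common]).mean())


def plot_test_bacc(result: ComparisonResult, path) -> None:
    """Simple per-model distribution plot of test balanced accuracy."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [result.test_bacc(m).to_numpy() for m in result.model_names]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(result.model_names) + 1),
                  labels=result.model_names)
    ax.set_ylabel("test balanced accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
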
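"""Classification performance statistics for risk-screening trees.

All models in this package are judged on *balanced accuracy*, the mean of
sensitivity and specificity.  With a minority positive class (POD prevalence
around 25%), optimising unweighted accuracy would sacrifice sensitivity; the
balanced criterion weights the two error types equally.

Fast-and-frugal trees additionally report frugality: ``mcu`` (mean cues used,
the average number of cue values looked up before a decision) and ``pci``
(percent cues ignored, ``1 - mcu / n_cues_available``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerfStats", "perf_from_predictions", "balanced_accuracy"]


def balanced_accuracy(sens: float, spec: float) -> float:
    """(sensitivity + specificity) / 2."""
    return (sens + spec) / 2.0


@dataclass(frozen=True)
class PerfStats:
    """Confusion counts plus the derived screening metrics.

    ``hi``/``mi``/``fa``/``cr`` are hit, miss, false-alarm and
    correct-rejection counts.  Ratios undefined on a single-class table are
    flagged as ``NaN``.  ``mcu``/``pci`` are ``None`` for models without a
    sequential cue-lookup semantics (e.g. logistic regression).
    """

    hi: int
    mi: int
    fa: int
    cr: int
    mcu: float | None = None
    n_cues_available: int | None = None

    def __post_init__(self) -> None:
        for name in ("hi", "mi", "fa", "cr"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative confusion count {name}")

    @property
    def n(self) -> int:
        return self.hi + self.mi + self.fa + self.cr

    @property
    def positives(self) -> int:
        return self.hi + self.mi

    @property
    def negatives(self) -> int:
        return self.fa + self.cr

    @property
    def sens(self) -> float:
        return self.hi / self.positives if self.positives else float("nan")

    @property
    def spec(self) -> float:
        return self.cr / self.negatives if self.negatives else float("nan")

    @property
    def bacc(self) -> float:
        return balanced_accuracy(self.sens, self.spec)

    @property
    def acc(self) -> float:
        return (self.hi + self.cr) / self.n if self.n else float("nan")

    @property
    def pci(self) -> float | None:
        if self.mcu is None or not self.n_cues_available:
            return None
        return 1.0 - self.mcu / self.n_cues_available

    def as_dict(self) -> dict:
        d = {"hi": self.hi, "mi": self.mi, "fa": self.fa, "cr": self.cr,
             "sens": self.sens, "spec": self.spec, "bacc": self.bacc, "acc": self.acc}
        if self.mcu is not None:
            d["mcu"] = self.mcu
            d["pci"] = self.pci
        return d

    def __str__(self) -> str:
        parts = [f"sens={self.sens:.3f}", f"spec={self.spec:.3f}",
                 f"bacc={self.bacc:.3f}", f"acc={self.acc:.3f}"]
        if self.mcu is not None:
            parts.append(f"mcu={self.mcu:.2f}")
            if self.pci is not None:
                parts.append(f"pci={100 * self.pci:.0f}%")
        return " ".join(parts)


def perf_from_predictions(y_true, y_pred, cues_used=None,
                          n_cues_available: int | None = None) -> PerfStats:
    """Tally confusion counts (and optionally cue-lookup counts) into PerfStats."""
    yt = np.asarray(y_true, dtype=bool)
    yp = np.asarray(y_pred, dtype=bool)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred have different lengths")
    hi = int(np.sum(yt & yp))
    mi = int(np.sum(yt & ~yp))
    fa = int(np.sum(~yt & yp))
    cr = int(np.sum(~yt & ~yp))
    mcu = float(np.mean(cues_used)) if cues_used is not None and len(yt) else None
    return PerfStats(hi, mi, fa, cr, mcu=mcu, n_cues_available=n_cues_available)
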
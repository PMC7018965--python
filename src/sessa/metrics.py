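"""Binary classification metrics for the benign/malignant setting.

Positive class = malignant = 1.  Two F1 variants are reported: the
harmonic mean of specificity and sensitivity (``f1_paper``, the formulation
used alongside the swarm selector in this line of work) and the standard
precision/recall harmonic mean (``f1_standard``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "metrics_from_confusion",
    "rmse",
    "r_squared",
    "feature_percentage",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1_paper: float
    f1_standard: float
    rmse: float
    confusion: ConfusionCounts
    r2: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d


def _check_binary(v, name: str) -> np.ndarray:
    a = np.asarray(v)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(int)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with malignant (1) as the positive class."""
    t = _check_binary(y_true, "y_true")
    p = _check_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, tag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(tag)
        return 0.0
    return num / den


def metrics_from_confusion(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision and both F1 variants
    from confusion counts.  Zero denominators yield a defined 0 and are
    flagged in ``degenerate``."""
    if c.n == 0:
        raise ValueError("confusion counts are empty")
    flags: list[str] = []
    acc = (c.tp + c.tn) / c.n
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", flags)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", flags)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    f1p = _ratio(2 * spec * sens, spec + sens, "f1_paper", flags)
    f1s = _ratio(2 * prec * sens, prec + sens, "f1_standard", flags)
    if flags:
        logger.info("degenerate denominators: %s", ", ".join(flags))
    err = (c.fp + c.fn) / c.n
    return MetricReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1_paper=f1p,
        f1_standard=f1s,
        rmse=math.sqrt(err),
        confusion=c,
        degenerate=flags,
    )


def rmse(y_target, y_output) -> float:
    """Root mean squared difference between target and output vectors."""
    t = np.asarray(y_target, dtype=float)
    o = np.asarray(y_output, dtype=float)
    if t.shape != o.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {o.shape}")
    if t.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((t - o) ** 2)))


def r_squared(y_target, y_output) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    t = np.asarray(y_target, dtype=float)
    o = np.asarray(y_output, dtype=float)
    if t.shape != o.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {o.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant target: R^2 undefined")
    ss_res = float(np.sum((t - o) ** 2))
    return 1.0 - ss_res / ss_tot


def feature_percentage(n_selected: int, n_total: int) -> str:
    """Human-readable retained-feature percentage, e.g. ``"4%"`` for
    1087/25088 and ``"4.4%"`` for 1115/25088.

    Values within 0.35 of an integer are printed as that integer, otherwise
    with one decimal (mirroring how such reduction tables are typically
    typeset).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must be in [0, n_total]")
    pct = 100.0 * n_selected / n_total
    nearest = round(pct)
    if abs(pct - nearest) < 0.35:
        return f"{nearest:d}%"
    return f"{round(pct, 1):g}%"
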
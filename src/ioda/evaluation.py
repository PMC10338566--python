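"""Confusion matrices, per-class metrics and the privacy-risk report.

The operational question behind every metric here is asymmetric: an
outside frame predicted inside is a potential privacy breach (patient or
staff visible in a video believed anonymized), while an inside frame
predicted outside merely costs usable footage.  Sensitivity of the
outside class therefore measures protection, its specificity measures
data retention, and :func:`privacy_report` converts both into expected
seconds at risk / seconds lost per video.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from ioda.annotation import BinaryClass, FrameClass, to_binary

BINARY_VOCABULARY = tuple(c.value for c in BinaryClass)
MULTICLASS_VOCABULARY = tuple(c.value for c in FrameClass)


def _token(label) -> str:
    """Class token for a FrameClass/BinaryClass member or plain string."""
    return label.value if hasattr(label, "value") else str(label)


@dataclass
class ConfusionMatrix:
    """C×C counts; rows are annotated (truth) classes, columns predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError(f"counts shape {self.counts.shape} != ({C}, {C})")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot add confusion matrices over different vocabularies")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    def row_fraction(self, truth: str, pred: str) -> float:
        """Share of frames annotated ``truth`` that were predicted ``pred``."""
        i = self.classes.index(_token(truth))
        j = self.classes.index(_token(pred))
        row = self.counts[i].sum()
        return float(self.counts[i, j] / row) if row else float("nan")


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single target class; NaN when undefined."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float


@dataclass(frozen=True)
class PrivacyReport:
    """Expected censoring errors for one video of given length and makeup."""

    duration_s: float
    outside_fraction: float
    at_risk_s: float  # outside footage predicted inside — the breach quantity
    lost_s: float  # inside footage predicted outside — needlessly censored

    @property
    def at_risk_display_s(self) -> int:
        return int(round(self.at_risk_s))

    @property
    def lost_display_s(self) -> int:
        return int(round(self.lost_s))


def confusion(
    truth: Sequence, pred: Sequence, vocabulary: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count (annotated, predicted) frame pairs over a fixed vocabulary."""
    truth = [_token(t) for t in truth]
    pred = [_token(p) for p in pred]
    if len(truth) != len(pred):
        raise ValueError(f"truth has {len(truth)} labels, pred has {len(pred)}")
    if vocabulary is None:
        seen = set(truth) | set(pred)
        if seen <= set(BINARY_VOCABULARY):
            vocabulary = BINARY_VOCABULARY
        elif seen <= set(MULTICLASS_VOCABULARY):
            vocabulary = MULTICLASS_VOCABULARY
        else:
            raise ValueError(f"labels outside known vocabularies: {sorted(seen)}")
    unknown = (set(truth) | set(pred)) - set(vocabulary)
    if unknown:
        raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")
    counts = _sk_confusion(truth, pred, labels=list(vocabulary))
    return ConfusionMatrix(tuple(vocabulary), counts)


def collapse_to_binary(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Sum a five-class matrix onto inside/outside along both axes."""
    if cm.classes != MULTICLASS_VOCABULARY:
        raise ValueError(f"expected the five-class vocabulary, got {cm.classes}")
    idx = [list(BINARY_VOCABULARY).index(to_binary(FrameClass(c)).value) for c in cm.classes]
    out = np.zeros((2, 2), dtype=np.int64)
    for i, bi in enumerate(idx):
        for j, bj in enumerate(idx):
            out[bi, bj] += cm.counts[i, j]
    return ConfusionMatrix(BINARY_VOCABULARY, out)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def metrics(cm: ConfusionMatrix, target_class: str) -> ClassMetrics:
    """One-vs-rest sensitivity/specificity/precision/F1 for ``target_class``."""
    i = cm.classes.index(_token(target_class))
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum() - tp)
    fp = int(cm.counts[:, i].sum() - tp)
    tn = cm.total - tp - fn - fp
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * prec * sens, prec + sens) if prec == prec and sens == sens else float("nan")
    return ClassMetrics(sensitivity=sens, specificity=spec, precision=prec, f1=f1)


def privacy_report(
    sensitivity: float,
    specificity: float,
    duration_s: float = 3600.0,
    outside_fraction: float = 0.172,
    sample_rate: float = 1.0,
) -> PrivacyReport:
    """Expected seconds at risk / lost for a video of given composition.

    ``at_risk_s`` is outside footage the classifier calls inside
    (escapes censoring); ``lost_s`` is inside footage called outside
    (censored needlessly).  Defaults describe a one-hour video that is
    17.2% outside.
    """
    if not 0 <= outside_fraction <= 1:
        raise ValueError("outside_fraction must be in [0, 1]")
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    at_risk = duration_s * outside_fraction * (1.0 - sensitivity)
    lost = duration_s * (1.0 - outside_fraction) * (1.0 - specificity)
    return PrivacyReport(
        duration_s=duration_s,
        outside_fraction=outside_fraction,
        at_risk_s=at_risk,
        lost_s=lost,
    )


@dataclass
class EvalReport:
    """Evaluation result for one experiment (one fold or pooled)."""

    cm: ConfusionMatrix
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)
    privacy: PrivacyReport | None = None

    @classmethod
    def from_labels(
        cls,
        truth: Sequence,
        pred: Sequence,
        vocabulary: Sequence[str] | None = None,
        duration_s: float = 3600.0,
    ) -> "EvalReport":
        cm = confusion(truth, pred, vocabulary)
        return cls.from_confusion(cm, duration_s=duration_s)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, duration_s: float = 3600.0) -> "EvalReport":
        per_class = {c: metrics(cm, c) for c in cm.classes}
        bin_cm = cm if cm.classes == BINARY_VOCABULARY else collapse_to_binary(cm)
        m_out = metrics(bin_cm, BinaryClass.OUTSIDE.value)
        outside_frac = _safe_div(bin_cm.counts[1].sum(), bin_cm.total)
        privacy = privacy_report(
            sensitivity=m_out.sensitivity,
            specificity=m_out.specificity,
            duration_s=duration_s,
            outside_fraction=outside_frac if outside_frac == outside_frac else 0.0,
        )
        return cls(cm=cm, per_class=per_class, privacy=privacy)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "classes": list(self.cm.classes),
            "counts": self.cm.counts.tolist(),
            "per_class": {
                c: {k: _round_or_none(getattr(m, k)) for k in ("sensitivity", "specificity", "precision", "f1")}
                for c, m in self.per_class.items()
            },
        }
        if self.privacy is not None:
            doc["privacy"] = {
                "duration_s": self.privacy.duration_s,
                "outside_fraction": round(self.privacy.outside_fraction, 4),
                "at_risk_s": self.privacy.at_risk_display_s,
                "lost_s": self.privacy.lost_display_s,
            }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        """Human-readable table: percentages at 2 decimals, F1 at 2 decimals."""
        width = max(len(c) for c in self.cm.classes)
        lines = ["confusion (rows = annotated, cols = predicted):"]
        header = " " * (width + 2) + "  ".join(f"{c:>{width}}" for c in self.cm.classes)
        lines.append(header)
        for c, row in zip(self.cm.classes, self.cm.counts):
            lines.append(f"{c:>{width}}  " + "  ".join(f"{v:>{width}d}" for v in row))
        lines.append("")
        lines.append(f"{'class':>{width}}  sens%   spec%   prec%   F1")
        for c, m in self.per_class.items():
            lines.append(
                f"{c:>{width}}  "
                f"{_pct(m.sensitivity)}  {_pct(m.specificity)}  {_pct(m.precision)}  "
                f"{'nan' if m.f1 != m.f1 else f'{m.f1:.2f}'}"
            )
        if self.privacy is not None:
            lines.append("")
            lines.append(
                f"privacy: {self.privacy.at_risk_display_s} s at risk, "
                f"{self.privacy.lost_display_s} s lost "
                f"(per {self.privacy.duration_s:.0f} s video, "
                f"{100 * self.privacy.outside_fraction:.1f}% outside)"
            )
        return "\n".join(lines)


def _pct(x: float) -> str:
    return "  nan" if x != x else f"{100 * x:6.2f}"


def _round_or_none(x: float):
    return None if x != x else round(x, 6)


def fold_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n−1) standard deviation across folds."""
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
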
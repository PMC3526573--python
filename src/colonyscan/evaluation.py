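"""Segmentation evaluation against reference annotations.

Pixel-level agreement is summarised by the F-score

    F = 2*TP / (2*TP + FP + FN),

and confluency estimation by the per-image error Delta = estimated -
reference confluency, summarised as bias (mean error, with a Student-t 95%
confidence interval), RMSE, and precision = sqrt(RMSE**2 - bias**2) — the
spread of the errors around their mean, so that precision**2 + bias**2 =
RMSE**2 holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "fscore",
    "confluency_report",
    "overlay",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts between a predicted and reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    """Per-image F-scores and confluency-error statistics over a test set."""

    fscores: np.ndarray
    mean_fscore: float
    sd_fscore: float
    confluency_errors: np.ndarray  # estimated - reference, per image
    bias: float
    bias_ci95: tuple[float, float] | None
    rmse: float
    precision: float


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not set(vals.tolist()) <= {0, 1}:
            raise ValueError(f"{name} mask must be binary")
        arr = arr.astype(bool)
    return arr


def confusion(pred_mask: np.ndarray, ref_mask: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between two same-shape binary masks."""
    pred = _as_binary(pred_mask, "predicted")
    ref = _as_binary(ref_mask, "reference")
    if pred.shape != ref.shape:
        raise ValueError(
            f"mask shapes differ: predicted {pred.shape} vs reference {ref.shape}"
        )
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def fscore(c: ConfusionCounts) -> float:
    """F-score 2TP/(2TP+FP+FN); undefined when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("F-score undefined: no positive pixels in either mask")
    return 2 * c.tp / denom


def confluency_report(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]] | Sequence,
    confidence: float = 0.95,
) -> EvaluationReport:
    """Summarise segmentation quality over (predicted, reference) mask pairs.

    For each image pair the F-score and the confluency error (estimated
    minus reference fraction of positive pixels) are computed; the report
    aggregates bias, its t-based confidence interval (omitted with a warning
    for fewer than two pairs), RMSE and precision.
    """
    fs: list[float] = []
    errors: list[float] = []
    for pred, ref in pairs:
        c = confusion(pred, ref)
        fs.append(fscore(c))
        errors.append((c.tp + c.fp) / c.total - (c.tp + c.fn) / c.total)
    if not fs:
        raise ValueError("no mask pairs supplied")
    f_arr = np.asarray(fs)
    e_arr = np.asarray(errors)
    n = len(e_arr)
    bias = float(e_arr.mean())
    rmse = float(np.sqrt(np.mean(e_arr**2)))
    precision = float(np.sqrt(max(rmse**2 - bias**2, 0.0)))
    if n >= 2:
        sem = e_arr.std(ddof=1) / np.sqrt(n)
        if sem > 0:
            lo, hi = stats.t.interval(confidence, n - 1, loc=bias, scale=sem)
        else:
            lo = hi = bias
        ci: tuple[float, float] | None = (float(lo), float(hi))
    else:
        warnings.warn("confidence interval omitted: fewer than 2 image pairs")
        ci = None
    return EvaluationReport(
        fscores=f_arr,
        mean_fscore=float(f_arr.mean()),
        sd_fscore=float(f_arr.std(ddof=1)) if n >= 2 else 0.0,
        confluency_errors=e_arr,
        bias=bias,
        bias_ci95=ci,
        rmse=rmse,
        precision=precision,
    )


def overlay(pred_mask: np.ndarray, ref_mask: np.ndarray) -> np.ndarray:
    """RGB agreement overlay: TP yellow, TN black, FP green, FN red."""
    pred = _as_binary(pred_mask, "predicted")
    ref = _as_binary(ref_mask, "reference")
    if pred.shape != ref.shape:
        raise ValueError("mask shapes differ")
    img = np.zeros(pred.shape + (3,), dtype=np.uint8)
    img[pred & ref] = (255, 255, 0)
    img[pred & ~ref] = (0, 255, 0)
    img[~pred & ref] = (255, 0, 0)
    return img
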
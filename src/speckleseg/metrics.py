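"""Denoising and segmentation quality metrics, plus the paired benchmark.

MSE  = (1/(h l)) sum (f - f_hat)^2
PSNR = 10 log10(pe_max^2 / MSE)     (dB; +inf when MSE = 0)
DSC  = 2 TP / (2 TP + FP + FN)
MCC  = (TP TN - FP FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
pixel error rate = (FP + FN) / total pixels  (frame-normalised, default) or
(FP + FN) / truth foreground ("foreground" convention).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError

__all__ = [
    "mse",
    "psnr",
    "confusion_counts",
    "dice",
    "mcc",
    "pixel_error_rate",
    "MetricsReport",
    "benchmark_suite",
]


def _pair(reference, test):
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise DimensionError(f"shape mismatch: {reference.shape} vs {test.shape}")
    return reference, test


def mse(reference, test) -> float:
    """Mean squared error between two images."""
    reference, test = _pair(reference, test)
    return float(np.mean(np.square(reference - test)))


def psnr(reference, test, pe_max: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    if pe_max <= 0:
        raise ValueError("pe_max must be > 0")
    err = mse(reference, test)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(pe_max ** 2 / err)


def _binary(mask, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1, 255, True, False))):
        raise ValueError(f"{name} must be binary (0/1 or 0/255), got values {uniq[:5]}")
    return mask > 0


def confusion_counts(pred_mask, truth_mask):
    """Pixel confusion counts (tp, fp, tn, fn) between binary masks."""
    pred = _binary(pred_mask, "pred_mask")
    truth = _binary(truth_mask, "truth_mask")
    if pred.shape != truth.shape:
        raise DimensionError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, fp, tn, fn


def dice(pred_mask, truth_mask) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN); 1.0 for two empty masks."""
    tp, fp, _, fn = confusion_counts(pred_mask, truth_mask)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def mcc(pred_mask, truth_mask) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = confusion_counts(pred_mask, truth_mask)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def pixel_error_rate(pred_mask, truth_mask, normalization: str = "frame") -> float:
    """Misclassified-pixel fraction.

    ``normalization="frame"`` divides by all pixels; ``"foreground"`` divides
    by the truth foreground area.
    """
    tp, fp, tn, fn = confusion_counts(pred_mask, truth_mask)
    if normalization == "frame":
        return (fp + fn) / (tp + fp + tn + fn)
    if normalization == "foreground":
        fg = tp + fn
        return math.inf if fg == 0 else (fp + fn) / fg
    raise ValueError("normalization must be 'frame' or 'foreground'")


@dataclass
class MetricsReport:
    """All metrics for one prediction, JSON-serialisable via ``to_dict``."""

    psnr: float | None
    mse: float | None
    dsc: float
    mcc: float
    error_rate: float
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_masks(cls, pred_mask, truth_mask, *, reference=None, test=None,
                   pe_max: float = 1.0,
                   error_normalization: str = "frame") -> "MetricsReport":
        tp, fp, tn, fn = confusion_counts(pred_mask, truth_mask)
        image_psnr = image_mse = None
        if reference is not None and test is not None:
            image_mse = mse(reference, test)
            image_psnr = psnr(reference, test, pe_max)
        return cls(psnr=image_psnr, mse=image_mse,
                   dsc=dice(pred_mask, truth_mask),
                   mcc=mcc(pred_mask, truth_mask),
                   error_rate=pixel_error_rate(pred_mask, truth_mask,
                                               error_normalization),
                   tp=tp, fp=fp, tn=tn, fn=fn)

    def to_dict(self) -> dict:
        return asdict(self)


def benchmark_suite(sigmas=(0.4, 0.8, 1.2), seeds=range(10),
                    methods=("snake", "cloud-acm"), *, shape=(128, 128),
                    error_normalization: str = "frame",
                    **pipeline_kwargs) -> pd.DataFrame:
    """Paired phantom benchmark of the two segmentation methods.

    For every (sigma, seed) cell one phantom is generated and denoised once,
    one PCNN initial contour is extracted, and every method is run from that
    identical initialisation — a paired design, so per-seed differences
    reflect the optimizer alone. Returns a tidy per-run DataFrame with
    columns sigma, seed, method, error_rate, dsc, mcc, psnr_noisy,
    psnr_denoised, mse_denoised, energy.
    """
    from .pipeline import run_phantom_trial

    rows = []
    for sigma in sigmas:
        for seed in seeds:
            rows.extend(run_phantom_trial(sigma=float(sigma), seed=int(seed),
                                          shape=shape, methods=methods,
                                          error_normalization=error_normalization,
                                          **pipeline_kwargs))
    return pd.DataFrame(rows)
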
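"""Plotting and image export helpers (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .registration import Hypercube


def _scale01(arr: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(arr, [1, 99])
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def composite_png(cube: Hypercube, path: str | Path) -> Path:
    """RGB mosaic assigning red/green/blue to the ADC/HBV/T2 channels."""
    mosaic = cube.mosaic
    rgb = np.stack([_scale01(mosaic[c]) for c in range(3)], axis=-1)
    path = Path(path)
    plt.imsave(path, rgb)
    return path


def detection_png(score_mosaic: np.ndarray, path: str | Path,
                  threshold: float | None = None) -> Path:
    """Grey-scale ACE score mosaic, optionally binarised at a threshold."""
    img = score_mosaic > threshold if threshold is not None else score_mosaic
    path = Path(path)
    plt.imsave(path, np.asarray(img, dtype=float), cmap="gray", vmin=0, vmax=1)
    return path


def sweep_plot(sweep, path: str | Path) -> Path:
    """R (red) and p-value (blue) against threshold, one panel per feature."""
    features = sweep["feature"].unique()
    fig, axes = plt.subplots(1, len(features), figsize=(4 * len(features), 3.2),
                             squeeze=False)
    for ax, feat in zip(axes[0], features):
        sub = sweep[sweep["feature"] == feat]
        ax.plot(sub["threshold"], sub["r"], "o-", color="red", label="R")
        ax2 = ax.twinx()
        ax2.plot(sub["threshold"], sub["p_value"], "s-", color="blue", label="p")
        ax.set_title(feat)
        ax.set_xlabel("ACE threshold")
        ax.set_ylabel("R", color="red")
        ax2.set_ylabel("p-value", color="blue")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def auc_histogram(aucs: np.ndarray, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(np.asarray(aucs, dtype=float), bins=25, color="steelblue")
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    for v in (lo, hi):
        ax.axvline(v, color="red", linestyle="--")
    ax.set_xlabel("AUC")
    ax.set_ylabel("count")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
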
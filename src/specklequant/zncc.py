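"""Zero-mean normalized cross-correlation demodulation.

ZNCC between a fixed reference specklegram and probe frames is the
sensor's scalar readout; grouping probes by concentration yields the
dose-response correlation curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["zncc", "correlation_curve"]

CURVE_COLUMNS = ["concentration_ng_per_ml", "mean_zncc", "sd_zncc", "n"]


def zncc(reference: np.ndarray, probe: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape images.

    ``sum((I0 - mean(I0)) * (I - mean(I))) / sqrt(sum((I0 - mean(I0))**2)
    * sum((I - mean(I))**2))``.  Symmetric, in [-1, 1], and invariant to
    positive affine brightness transforms of either image.  Raises on a
    zero-variance input rather than returning a silent 0.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(probe, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(np.sum(da * da))
    ssb = float(np.sum(db * db))
    if ssa == 0.0 or ssb == 0.0:
        raise ValueError("ZNCC undefined for zero-variance image")
    return float(np.sum(da * db) / np.sqrt(ssa * ssb))


def correlation_curve(
    reference: np.ndarray,
    manifest: pd.DataFrame,
    images: np.ndarray,
) -> pd.DataFrame:
    """Per-concentration ZNCC statistics against a fixed reference frame.

    ``images`` is the stack aligned with ``manifest`` rows.  Returns a
    DataFrame with columns ``concentration_ng_per_ml, mean_zncc, sd_zncc,
    n`` ordered by concentration.
    """
    if len(manifest) != len(images):
        raise ValueError("manifest and image stack lengths differ")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    values = np.array([zncc(reference, img) for img in images])
    df = pd.DataFrame(
        {
            "concentration_ng_per_ml": manifest[
                "concentration_ng_per_ml"
            ].to_numpy(),
            "zncc": values,
        }
    )
    grouped = (
        df.groupby("concentration_ng_per_ml")["zncc"]
        .agg(mean_zncc="mean", sd_zncc="std", n="size")
        .reset_index()
        .sort_values("concentration_ng_per_ml", ignore_index=True)
    )
    grouped["sd_zncc"] = grouped["sd_zncc"].fillna(0.0)
    return grouped[CURVE_COLUMNS]
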
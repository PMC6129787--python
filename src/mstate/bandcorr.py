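"""Correlation between microstate GFP and frequency-band power.

For each class and band, the GFP values at samples carrying the class's
label are paired with the channel-averaged band power at the same samples
and summarized by Pearson's correlation coefficient

    rho_xy = sum (x_i - x̄)(y_i - ȳ) / sqrt(sum (x_i - x̄)² · sum (y_i - ȳ)²).

Band power is the squared band-passed signal, averaged over channels and
smoothed with a moving average (250 ms by default).  The default bands are
delta 1–4, theta 4–8, mu/alpha 8–14, beta 14–20, and gamma 20–40 Hz; the
historically tabulated 14–20 Hz theta (a duplicate of beta) remains
selectable via ``literal_theta=True`` for literal replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .gfp import GFPSeries
from .io_preprocess import Recording, bandpass_fir
from .segment import LabelSeries

__all__ = ["BandDefinition", "default_bands", "band_power_series",
           "pearson_r", "microstate_band_correlogram"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float      # Hz
    high: float     # Hz

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")


def default_bands(literal_theta: bool = False) -> list:
    theta = BandDefinition("theta", 14.0, 20.0) if literal_theta \
        else BandDefinition("theta", 4.0, 8.0)
    return [
        BandDefinition("delta", 1.0, 4.0),
        theta,
        BandDefinition("mu", 8.0, 14.0),
        BandDefinition("beta", 14.0, 20.0),
        BandDefinition("gamma", 20.0, 40.0),
    ]


def band_power_series(rec: Recording, band: BandDefinition,
                      smooth_ms: float = 250.0,
                      transition_hz: float = 1.0) -> np.ndarray:
    """Channel-averaged instantaneous power in one frequency band.

    Each channel is band-passed with the same zero-phase FIR design as the
    preprocessing chain, squared, averaged across channels, and smoothed
    with a ``smooth_ms`` moving average.
    """
    if band.high >= rec.sampling_rate / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist")
    filtered = bandpass_fir(rec, band.low, band.high,
                            transition_hz=transition_hz)
    power = (filtered.data ** 2).mean(axis=0)
    width = max(1, int(round(smooth_ms / 1000.0 * rec.sampling_rate)))
    return uniform_filter1d(power, size=width, mode="nearest")


def pearson_r(x, y) -> float:
    """Pearson's correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx <= 0 or sy <= 0:
        raise ValueError("zero-variance input")
    return float(dx @ dy / np.sqrt(sx * sy))


def microstate_band_correlogram(ls: LabelSeries, gfp: GFPSeries,
                                rec: Recording, bands=None,
                                smooth_ms: float = 250.0,
                                class_names: dict | None = None,
                                min_samples: int = 3) -> pd.DataFrame:
    """Correlation of each microstate's GFP with each band's power.

    x = GFP restricted to samples labeled with the class, y = band power at
    the same samples.  Classes with fewer than ``min_samples`` labeled
    samples are omitted.  Returns a (class, band, rho, n) table.
    """
    bands = bands if bands is not None else default_bands()
    powers = {b.name: band_power_series(rec, b, smooth_ms) for b in bands}
    rows = []
    for cid in range(int(ls.labels.max()) + 1):
        mask = ls.labels == cid
        n = int(mask.sum())
        if n < min_samples:
            continue
        x = gfp.values[mask]
        for b in bands:
            y = powers[b.name][mask]
            try:
                rho = pearson_r(x, y)
            except ValueError:
                rho = float("nan")
            name = class_names.get(cid, str(cid)) if class_names else str(cid)
            rows.append({"class": name, "band": b.name, "rho": rho, "n": n})
    return pd.DataFrame(rows)
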
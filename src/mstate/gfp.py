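"""Global field power (GFP) and its local maxima.

The GFP at time t is the spatial standard deviation of the scalp map:

    GFP(t) = sqrt( sum_i (V_i(t) - V_mean(t))^2 / k )

where ``V_i(t)`` is the potential of electrode i, ``V_mean(t)`` the mean
over the k electrodes.  Instants of locally maximal GFP carry the highest
topographic signal-to-noise ratio and are the maps entered into microstate
clustering.  A local maximum here is a sample whose GFP strictly exceeds
the 4 preceding and 4 following samples (``flank`` configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GFPSeries", "PeakSet", "compute_gfp", "find_gfp_peaks"]


@dataclass
class GFPSeries:
    """Per-sample global field power of a multichannel recording."""

    values: np.ndarray          # (n_samples,), µV, >= 0
    sampling_rate: float        # Hz
    n_channels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("GFP values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PeakSet:
    """Local maxima of a GFP series with their (mean-removed) topographies."""

    indices: np.ndarray         # sorted sample indices of the peaks
    maps: np.ndarray            # (n_peaks, n_channels), channel-mean removed
    gfp_at_peak: np.ndarray     # (n_peaks,) µV
    strata: np.ndarray | None = None   # optional labels (e.g. condition) per peak

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.gfp_at_peak = np.asarray(self.gfp_at_peak, dtype=float)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def to_frame(self, channel_names=None) -> pd.DataFrame:
        """Serialize to a table (index, gfp, one column per channel)."""
        names = channel_names or [f"ch{i}" for i in range(self.n_channels)]
        df = pd.DataFrame(self.maps, columns=list(names))
        df.insert(0, "gfp", self.gfp_at_peak)
        df.insert(0, "index", self.indices)
        if self.strata is not None:
            df["stratum"] = self.strata
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakSet":
        strata = df["stratum"].to_numpy() if "stratum" in df.columns else None
        chan_cols = [c for c in df.columns if c not in ("index", "gfp", "stratum")]
        return cls(
            indices=df["index"].to_numpy(),
            maps=df[chan_cols].to_numpy(dtype=float),
            gfp_at_peak=df["gfp"].to_numpy(dtype=float),
            strata=strata,
        )


def concatenate_peaks(peaksets, strata=None) -> PeakSet:
    """Pool several PeakSets (e.g. one per condition) into one.

    ``strata`` optionally gives one label per input set, recorded per peak so
    stratified cross-validation splits can respect the pooling structure.
    Indices are kept per-source (they are not re-offset); pooled sets are
    meant for clustering, where temporal position is irrelevant.
    """
    maps = np.vstack([p.maps for p in peaksets])
    gfps = np.concatenate([p.gfp_at_peak for p in peaksets])
    if strata is not None:
        labels = np.concatenate(
            [np.repeat(s, len(p)) for s, p in zip(strata, peaksets)]
        )
    else:
        labels = None
    # indices become a running count — uniqueness matters, position does not
    idx = np.arange(maps.shape[0])
    return PeakSet(indices=idx, maps=maps, gfp_at_peak=gfps, strata=labels)


def compute_gfp(rec) -> GFPSeries:
    """GFP of a Recording (population standard deviation across channels)."""
    data = np.asarray(rec.data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    values = data.std(axis=0, ddof=0)
    return GFPSeries(values=values, sampling_rate=rec.sampling_rate,
                     n_channels=data.shape[0])


def find_gfp_peaks(g: GFPSeries, rec=None, flank: int = 4) -> PeakSet:
    """Local GFP maxima: samples strictly greater than the ``flank``
    preceding and following samples.

    Ties/plateaus never qualify (strict inequality), and the first/last
    ``flank`` samples are excluded because they lack a full neighborhood.
    When ``rec`` is given, peak topographies are extracted from it with the
    channel mean removed; otherwise ``maps`` is an empty (n, 0) array.
    """
    v = g.values
    n = v.size
    if n <= 2 * flank:
        raise ValueError(f"series of length {n} too short for flank {flank}")
    ok = np.ones(n - 2 * flank, dtype=bool)
    center = v[flank : n - flank]
    for j in range(1, flank + 1):
        ok &= center > v[flank - j : n - flank - j]
        ok &= center > v[flank + j : n - flank + j]
    idx = np.nonzero(ok)[0] + flank
    if rec is not None:
        data = np.asarray(rec.data, dtype=float)
        maps = data[:, idx].T
        maps = maps - maps.mean(axis=1, keepdims=True)
    else:
        maps = np.empty((idx.size, 0))
    return PeakSet(indices=idx, maps=maps, gfp_at_peak=v[idx])
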
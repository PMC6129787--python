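"""Backfitting microstate templates to the full time series.

Each GFP peak takes the class of its best-matching template; every other
sample inherits the label of the temporally nearest peak (region filling
of the GFP curve between peaks), so the whole analysis window is labeled
and time coverages sum to 100%.  The resulting label series is summarized
as maximal runs, and the ordered run labels form the microstate syntax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import TemplateSet, normalize_maps, _corr_matrix
from .gfp import GFPSeries, PeakSet

__all__ = [
    "LabelSeries", "Syntax",
    "backfit", "smooth_runs", "extract_syntax",
    "runs_from_labels", "labels_from_runs", "first_occurrence_names",
]


@dataclass
class LabelSeries:
    """Per-sample microstate class ids with their maximal runs."""

    labels: np.ndarray              # (n_samples,) int class ids
    sampling_rate: float
    runs: list = field(default_factory=list)   # (class_id, start, length)
    window_ms: float | None = None  # WT, the analysis window

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.runs:
            self.runs = runs_from_labels(self.labels)
        if self.window_ms is None:
            self.window_ms = self.labels.size / self.sampling_rate * 1000.0

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def to_frame(self, names: dict | None = None) -> pd.DataFrame:
        lab = [names.get(i, str(i)) for i in self.labels] if names \
            else self.labels
        return pd.DataFrame({"sample": np.arange(self.n_samples), "class": lab})


@dataclass
class Syntax:
    """Run-level class sequence and adjacent-transition counts."""

    sequence: list                     # class id per run, in temporal order
    transition_counts: np.ndarray      # (n_classes, n_classes)

    def to_json(self, names: dict | None = None) -> str:
        seq = [names.get(c, str(c)) for c in self.sequence] if names \
            else list(map(int, self.sequence))
        return json.dumps({"sequence": seq,
                           "transition_counts": self.transition_counts.tolist()})


def runs_from_labels(labels: np.ndarray) -> list:
    """Maximal runs (class_id, start, length) tiling the label series."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.nonzero(np.diff(labels))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def labels_from_runs(runs: list) -> np.ndarray:
    return np.concatenate([np.full(length, cid, dtype=int)
                           for cid, _, length in runs])


def backfit(rec, gfp: GFPSeries, peaks: PeakSet, templates: TemplateSet,
            mode: str = "nearest_peak") -> LabelSeries:
    """Label every sample with a microstate class.

    ``nearest_peak`` (default): each peak map is assigned to its
    best-matching template and every non-peak sample inherits the label of
    the temporally nearest peak (ties go to the earlier peak; samples
    before the first / after the last peak extend its label).
    ``per_sample``: each sample is labeled by its own best-matching
    template.
    """
    n = rec.data.shape[1]
    Tn = normalize_maps(templates.maps)
    invariant = templates.polarity_mode == "invariant"
    if mode == "per_sample":
        # safe normalization: a (near-)flat map correlates 0 with everything
        X = np.asarray(rec.data.T, dtype=float)
        X = X - X.mean(axis=1, keepdims=True)
        g = X.std(axis=1, ddof=0)
        X = X / np.maximum(g, 1e-12)[:, None]
        C = _corr_matrix(X, Tn)
        S = np.abs(C) if invariant else C
        labels = S.argmax(axis=1)
    elif mode == "nearest_peak":
        if len(peaks) == 0:
            raise ValueError("nearest_peak backfitting needs at least one peak")
        Xp = normalize_maps(peaks.maps)
        C = _corr_matrix(Xp, Tn)
        S = np.abs(C) if invariant else C
        peak_labels = S.argmax(axis=1)
        idx = peaks.indices
        t = np.arange(n)
        pos = np.searchsorted(idx, t)           # first peak index >= t
        left = np.clip(pos - 1, 0, idx.size - 1)
        right = np.clip(pos, 0, idx.size - 1)
        d_left = np.abs(t - idx[left])
        d_right = np.abs(idx[right] - t)
        use_left = d_left <= d_right            # tie -> earlier peak
        nearest = np.where(use_left, left, right)
        labels = peak_labels[nearest]
    else:
        raise ValueError(f"unknown backfit mode: {mode!r}")
    return LabelSeries(labels=labels, sampling_rate=gfp.sampling_rate)


def peak_class_labels(peaks: PeakSet, templates: TemplateSet) -> np.ndarray:
    """Class id of each GFP peak (best-matching template)."""
    C = _corr_matrix(normalize_maps(peaks.maps), normalize_maps(templates.maps))
    S = np.abs(C) if templates.polarity_mode == "invariant" else C
    return S.argmax(axis=1)


def smooth_runs(ls: LabelSeries, min_duration_ms: float = 0.0,
                rec=None, templates: TemplateSet | None = None) -> LabelSeries:
    """Absorb runs shorter than ``min_duration_ms`` into a neighbor.

    The absorbing neighbor is the one whose template correlates better with
    the short run's mean map (when ``rec`` and ``templates`` are given),
    otherwise the longer neighbor.  Applied repeatedly until stable, so the
    operation is idempotent.  ``min_duration_ms = 0`` is the identity.
    """
    if min_duration_ms <= 0:
        return ls
    min_len = int(np.ceil(min_duration_ms * ls.sampling_rate / 1000.0))
    runs = list(ls.runs)
    changed = True
    while changed:
        changed = False
        if len(runs) <= 1:
            break
        lengths = [r[2] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        cid, start, length = runs[i]
        neighbors = []
        if i > 0:
            neighbors.append(i - 1)
        if i < len(runs) - 1:
            neighbors.append(i + 1)
        if rec is not None and templates is not None and len(neighbors) == 2:
            seg = rec.data[:, start:start + length].mean(axis=1)
            from .cluster import spatial_correlation
            scores = [spatial_correlation(seg, templates.maps[runs[j][0]],
                                          templates.polarity_mode)
                      for j in neighbors]
            j = neighbors[int(np.argmax(scores))]
        else:
            j = max(neighbors, key=lambda jj: runs[jj][2])
        runs[i] = (runs[j][0], start, length)
        # merge adjacent equal-class runs
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                pc, ps, pl = merged[-1]
                merged[-1] = (pc, ps, pl + r[2])
            else:
                merged.append(r)
        runs = merged
        changed = True
    labels = labels_from_runs(runs)
    return LabelSeries(labels=labels, sampling_rate=ls.sampling_rate,
                       window_ms=ls.window_ms)


def extract_syntax(ls: LabelSeries) -> Syntax:
    """Ordered run labels and counts of adjacent class transitions."""
    if not ls.runs:
        raise ValueError("label series has no runs")
    seq = [cid for cid, _, _ in ls.runs]
    n_classes = int(max(seq)) + 1
    counts = np.zeros((n_classes, n_classes), dtype=int)
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a, b] += 1
    return Syntax(sequence=seq, transition_counts=counts)


def first_occurrence_names(ls: LabelSeries, alphabet: str = "ABCDEFGHIJ") -> dict:
    """Map class ids to letters by order of first temporal occurrence."""
    names: dict[int, str] = {}
    for cid in ls.labels:
        cid = int(cid)
        if cid not in names:
            names[cid] = alphabet[len(names)]
    return names
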
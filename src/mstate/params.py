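"""Microstate parameters per class: duration, occurrence, coverage, amplitude.

For each class within the analysis window WT (3.5 s by default):

    MST  total labeled time of the class (ms)
    CON  number of maximal runs (continuous occurrences)
    Dur  = MST / CON                         mean run duration (ms)
    TC   = MST / WT × 100                    time coverage (%)
    GFPP sum of the GFP values at the class's peaks (µV)
    Amp  = GFPP / occurrence_count           mean peak amplitude (µV)

Occurrence is the number of GFP peaks assigned to the class; it is
reported both as a raw count within WT and per second (the two readings
of the original "/s" tabulation are not mutually consistent, so both are
kept).  ``amp_denominator`` switches the amplitude denominator between the
peak count (default; yields µV-scale mean peak amplitudes) and CON (the
literal ratio of summed peak GFP to run count).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gfp import GFPSeries, PeakSet
from .segment import LabelSeries

__all__ = ["microstate_parameters"]


def microstate_parameters(ls: LabelSeries, gfp: GFPSeries | None = None,
                          peaks: PeakSet | None = None,
                          peak_labels=None, wt_ms: float = 3500.0,
                          amp_denominator: str = "peak_count",
                          class_names: dict | None = None,
                          n_classes: int | None = None) -> pd.DataFrame:
    """Per-class microstate parameters of one labeled recording.

    ``wt_ms`` must match the labeled window within one sample period; the
    effective window (n_samples / rate) is used as the TC denominator so
    coverages sum to exactly 100% when every sample is labeled.  Classes
    with zero labeled time get a flagged all-zero record.
    """
    if amp_denominator not in ("con", "peak_count"):
        raise ValueError("amp_denominator must be 'con' or 'peak_count'")
    fs = ls.sampling_rate
    wt_eff = ls.n_samples / fs * 1000.0
    if abs(wt_eff - wt_ms) > 1000.0 / fs + 1e-9:
        raise ValueError(
            f"labeled window is {wt_eff:.2f} ms but wt_ms={wt_ms:.2f}; "
            "pass the window actually labeled")
    if n_classes is None:
        n_classes = int(ls.labels.max()) + 1
    if peaks is not None and peak_labels is None:
        raise ValueError("peak_labels required when peaks are given")

    sample_ms = 1000.0 / fs
    rows = []
    for cid in range(n_classes):
        mst_ms = float(np.sum(ls.labels == cid)) * sample_ms
        con = sum(1 for r in ls.runs if r[0] == cid)
        if peaks is not None:
            on_class = np.asarray(peak_labels) == cid
            occ = int(np.sum(on_class))
            gfpp = float(peaks.gfp_at_peak[on_class].sum())
        else:
            occ, gfpp = 0, float("nan")
        if con == 0:
            rows.append({
                "class": cid, "mst_ms": 0.0, "con": 0, "duration_ms": 0.0,
                "occurrence_count": occ, "occurrence_per_s": occ / (wt_eff / 1000.0),
                "time_coverage_pct": 0.0, "gfpp_uV": gfpp,
                "amplitude_uV": 0.0, "wt_ms": wt_eff, "empty_class": True,
            })
            continue
        dur = mst_ms / con
        tc = mst_ms / wt_eff * 100.0
        denom = con if amp_denominator == "con" else occ
        amp = gfpp / denom if denom > 0 else 0.0
        rows.append({
            "class": cid, "mst_ms": mst_ms, "con": con, "duration_ms": dur,
            "occurrence_count": occ, "occurrence_per_s": occ / (wt_eff / 1000.0),
            "time_coverage_pct": tc, "gfpp_uV": gfpp, "amplitude_uV": amp,
            "wt_ms": wt_eff, "empty_class": False,
        })
    df = pd.DataFrame(rows)
    if class_names:
        df["class"] = [class_names.get(c, str(c)) for c in df["class"]]
    # machine check of the defining identity Dur × CON = MST (hence
    # Dur·CON/WT = TC) on every emitted record
    occupied = ~df["empty_class"]
    assert np.allclose(df.loc[occupied, "duration_ms"] * df.loc[occupied, "con"],
                       df.loc[occupied, "mst_ms"], atol=1e-9)
    return df


def params_long_format(df: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Reshape a per-class parameter table to long (condition, class,
    parameter, value) rows for reporting."""
    keep = ["duration_ms", "occurrence_count", "occurrence_per_s",
            "time_coverage_pct", "amplitude_uV", "mst_ms", "con", "gfpp_uV"]
    out = df.melt(id_vars=["class"], value_vars=keep,
                  var_name="parameter", value_name="value")
    out.insert(0, "condition", condition)
    return out
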
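"""Reading EEG recordings and the preprocessing chain.

The chain, in order: import → downsample (125 Hz default) → zero-phase FIR
band-pass (0.05–45 Hz default) → epoch extraction around task onset →
baseline correction → artifact hook (external bad-trial mask; no ICA) →
re-reference to the common average → averaging of same-condition trials.

Two on-disk formats are supported: EDF for continuous recordings (read via
MNE, written by the package's own 16-bit writer) and delimited channels×time
matrices whose first row lists the channel names.  Events are a 3-column
delimited table (onset_sample, condition, trial_id); a montage is a
delimited (name, x, y[, z]) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import _edf

__all__ = [
    "Recording", "EpochSet",
    "read_recording", "write_recording", "read_events", "read_montage",
    "bandpass_fir", "downsample", "epoch_baseline_reref", "artifact_hook",
    "average_trials", "preprocess",
]

#: canonical stage order of the preprocessing chain
PIPELINE_ORDER = ("import", "downsample", "filter", "epoch", "baseline",
                  "artifact_hook", "rereference", "average")


@dataclass
class Recording:
    """A channels×samples EEG matrix in µV with its sampling rate."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list = field(default_factory=list)
    montage: np.ndarray | None = None      # per-channel 2-D/3-D positions
    reference: str = "original"            # or "common_average"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal channel count")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Recording":
        base = dict(data=self.data, sampling_rate=self.sampling_rate,
                    channel_names=list(self.channel_names),
                    montage=self.montage, reference=self.reference)
        base.update(kw)
        return Recording(**base)


@dataclass
class EpochSet:
    """Trials × channels × samples array around task onsets."""

    epochs: np.ndarray
    sampling_rate: float
    time_zero: int                    # sample index of task onset within epoch
    conditions: list                  # one label per trial
    channel_names: list = field(default_factory=list)
    baseline_window: tuple | None = None   # (start ms, end ms) rel. onset

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials×channels×samples")
        if not 0 <= self.time_zero < self.epochs.shape[2]:
            raise ValueError("time_zero must lie inside the epoch")
        if len(self.conditions) != self.epochs.shape[0]:
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


# ---------------------------------------------------------------- file I/O

def _read_delimited(path) -> tuple[list, np.ndarray]:
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise ValueError(f"{path}: empty file")
    sep = "\t" if "\t" in text[0] else ","
    names = [c.strip() for c in text[0].split(sep)]
    rows = []
    for ln in text[1:]:
        if not ln.strip():
            continue
        rows.append([float(x) for x in ln.split(sep)])
    if len(rows) != len(names):
        raise ValueError(
            f"{path}: header names {len(names)} channels but file has "
            f"{len(rows)} data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: non-rectangular matrix")
    return names, np.array(rows, dtype=float)


def read_recording(path, format: str = "auto",
                   sampling_rate: float | None = None) -> Recording:
    """Read an EDF file or a delimited channels×time matrix.

    Delimited files carry no rate, so ``sampling_rate`` must be supplied
    for them (defaults to 125 Hz, the pipeline's working rate).  EDF data
    are converted from Volts (MNE's internal unit) back to µV.
    """
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(data=raw.get_data() * 1e6,
                         sampling_rate=float(raw.info["sfreq"]),
                         channel_names=list(raw.ch_names))
    if format == "delimited":
        names, data = _read_delimited(path)
        return Recording(data=data, sampling_rate=sampling_rate or 125.0,
                         channel_names=names)
    raise ValueError(f"unsupported format: {format}")


def write_recording(path, rec: Recording, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        _edf.write_edf(path, rec.data, rec.sampling_rate, rec.channel_names)
    elif format == "delimited":
        with open(path, "w") as fh:
            fh.write(",".join(rec.channel_names) + "\n")
            for row in rec.data:
                fh.write(",".join(f"{x:.8g}" for x in row) + "\n")
    else:
        raise ValueError(f"unsupported format: {format}")


def read_events(path) -> pd.DataFrame:
    """Events table: onset_sample, condition, trial_id (tab/comma separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"onset_sample", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    return df


def read_montage(path) -> pd.DataFrame:
    """Montage table: name, x, y[, z]."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "name" not in df.columns or "x" not in df.columns:
        raise ValueError("montage table must have at least columns name, x, y")
    return df


# ------------------------------------------------------------ filtering

def _fir_taps(low: float, high: float, fs: float, numtaps: int | None,
              transition_hz: float = 0.5) -> np.ndarray:
    if numtaps is None:
        numtaps = int(np.ceil(3.3 * fs / transition_hz)) | 1
    else:
        numtaps = int(numtaps) | 1
    if low > 0:
        return signal.firwin(numtaps, [low, high], pass_zero=False,
                             fs=fs, window="hamming")
    return signal.firwin(numtaps, high, pass_zero=True, fs=fs, window="hamming")


def _filtfilt(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), data.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def bandpass_fir(rec: Recording, low: float = 0.05, high: float = 45.0,
                 order: int | None = None, transition_hz: float = 0.5) -> Recording:
    """Zero-phase windowed-sinc (Hamming) band-pass.

    Applied forward-backward (``filtfilt``) so the effective magnitude
    response is squared and the phase is exactly zero.  The default tap
    count targets a 0.5 Hz transition width at the low edge.  A high-pass
    edge as low as 0.05 Hz cannot be realized sharply by a finite-length
    window at these tap counts, so when ``low > 0`` each channel is
    demeaned first: the DC component is removed exactly and the FIR handles
    the remaining drift.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 <= low < high < nyq:
        raise ValueError(f"band edges ({low}, {high}) violate Nyquist {nyq}")
    data = rec.data
    if low > 0:
        data = data - data.mean(axis=-1, keepdims=True)
    taps = _fir_taps(low, high, rec.sampling_rate, order, transition_hz)
    return rec.copy_with(data=_filtfilt(taps, data))


def downsample(rec: Recording, target: float = 125.0) -> Recording:
    """Resample to ``target`` Hz with anti-alias low-pass at 0.4 × target.

    Integer ratios decimate after an explicit FIR low-pass; rational ratios
    go through polyphase resampling.
    """
    if target >= rec.sampling_rate:
        raise ValueError("target rate must be below the current rate")
    ratio = rec.sampling_rate / target
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        taps = signal.firwin(int(np.ceil(6.6 * q)) | 1, 0.4 * target,
                             fs=rec.sampling_rate, window="hamming")
        filtered = _filtfilt(taps, rec.data)
        data = filtered[:, ::q]
    else:
        from fractions import Fraction
        frac = Fraction(target / rec.sampling_rate).limit_denominator(1000)
        data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                    axis=-1)
    return rec.copy_with(data=data, sampling_rate=target)


# ------------------------------------------------------------- epoching

def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def epoch_baseline_reref(rec: Recording, events: pd.DataFrame,
                         epoch_window: tuple = (-1500.0, 3500.0),
                         baseline_window: tuple = (-1500.0, 500.0)) -> EpochSet:
    """Extract epochs, baseline-correct, and re-reference to common average.

    Per trial: the window (ms, relative to the event onset sample) is cut
    out, each channel's mean over the baseline window is subtracted, and
    each sample's channel mean is removed (common average reference, under
    which GFP is unchanged).
    """
    fs = rec.sampling_rate
    i0 = _ms_to_samples(epoch_window[0], fs)
    i1 = _ms_to_samples(epoch_window[1], fs)
    b0 = _ms_to_samples(baseline_window[0], fs)
    b1 = _ms_to_samples(baseline_window[1], fs)
    if not (i0 <= b0 < b1 <= i1):
        raise ValueError("baseline window must lie inside the epoch window")
    epochs, conds = [], []
    for _, ev in events.iterrows():
        onset = int(ev["onset_sample"])
        lo, hi = onset + i0, onset + i1
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"event at sample {onset} needs samples [{lo}, {hi}) outside "
                f"the recording of length {rec.n_samples}")
        ep = rec.data[:, lo:hi].copy()
        base = ep[:, (b0 - i0):(b1 - i0)].mean(axis=1, keepdims=True)
        ep -= base
        ep -= ep.mean(axis=0, keepdims=True)     # common average reference
        epochs.append(ep)
        conds.append(str(ev["condition"]))
    return EpochSet(epochs=np.array(epochs), sampling_rate=fs, time_zero=-i0,
                    conditions=conds, channel_names=list(rec.channel_names),
                    baseline_window=tuple(baseline_window))


def artifact_hook(epochs: EpochSet, bad_trials=None) -> EpochSet:
    """Pass-through artifact stage: drop externally flagged trials.

    ICA-based artifact identification is delegated to external tooling;
    this hook only honors a boolean mask or index list of bad trials.
    """
    if bad_trials is None:
        return epochs
    bad = np.zeros(epochs.n_trials, dtype=bool)
    bad[np.asarray(bad_trials)] = True
    keep = ~bad
    return EpochSet(epochs=epochs.epochs[keep],
                    sampling_rate=epochs.sampling_rate,
                    time_zero=epochs.time_zero,
                    conditions=[c for c, k in zip(epochs.conditions, keep) if k],
                    channel_names=epochs.channel_names,
                    baseline_window=epochs.baseline_window)


def average_trials(epochs: EpochSet, condition: str) -> Recording:
    """Element-wise mean across all trials of one condition."""
    mask = [c == condition for c in epochs.conditions]
    if not any(mask):
        raise ValueError(f"unknown condition label: {condition!r}")
    mean = epochs.epochs[np.asarray(mask)].mean(axis=0)
    return Recording(data=mean, sampling_rate=epochs.sampling_rate,
                     channel_names=list(epochs.channel_names),
                     reference="common_average")


def preprocess(rec: Recording, events: pd.DataFrame,
               target_rate: float = 125.0, low: float = 0.05,
               high: float = 45.0, epoch_window=(-1500.0, 3500.0),
               baseline_window=(-1500.0, 500.0), bad_trials=None) -> EpochSet:
    """The full chain in canonical order (downsample → filter → epoch →
    baseline → artifact hook → re-reference), onset samples rescaled to the
    target rate."""
    if target_rate < rec.sampling_rate:
        factor = target_rate / rec.sampling_rate
        rec = downsample(rec, target_rate)
        events = events.assign(
            onset_sample=(events["onset_sample"] * factor).round().astype(int))
    rec = bandpass_fir(rec, low, high)
    eps = epoch_baseline_reref(rec, events, epoch_window, baseline_window)
    return artifact_hook(eps, bad_trials)
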
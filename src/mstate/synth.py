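"""Synthetic multichannel EEG with planted microstate structure.

A recording is built from a small set of quasi-stable scalp topographies
(the planted microstate classes) that switch in a configured order, for
example A for the 0–500 ms task-preparation period, then B, then C, as in
a hand-grip force task where the B→C transition moves earlier and the
overall amplitude grows as the force target rises.  The active template is
multiplied by a signed mixture of band-limited carriers (mu/beta by
default), so the signal genuinely oscillates in those bands and GFP peaks
occur throughout every segment; white Gaussian sensor noise is added at a
configured signal-to-noise amplitude ratio.

Everything downstream of the generator (peak picking, clustering,
backfitting, parameter estimation) can therefore be validated against the
exact planted labels and templates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SimTemplateSet",
    "SimPlan",
    "SimRecording",
    "StudyConfig",
    "make_templates",
    "synthesize_recording",
    "simulate_study",
    "default_conditions",
    "schedule_to_labels",
    "write_study",
]

#: amplitude scales per condition (mean GFP presets, µV): executed then
#: imagined, for 4/10/16 kg force targets.
AMPLITUDE_PRESETS = {
    ("executed", 4): 2.16, ("executed", 10): 2.82, ("executed", 16): 3.54,
    ("imagined", 4): 1.82, ("imagined", 10): 2.18, ("imagined", 16): 3.37,
}

#: duration of the planted B segment (ms); the B→C switch moves earlier as
#: the force target rises, while A always occupies the 0–500 ms preparation
#: period.
B_DURATION_PRESETS = {
    ("executed", 4): 2008, ("executed", 10): 1543, ("executed", 16): 1254,
    ("imagined", 4): 2220, ("imagined", 10): 1762, ("imagined", 16): 1562,
}


@dataclass
class SimTemplateSet:
    """Planted class topographies: one zero-mean, unit-GFP row per class."""

    maps: np.ndarray            # (n_classes, n_channels)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class SimPlan:
    """Recipe for one synthetic trial."""

    sampling_rate: float = 125.0
    window_ms: float = 3500.0
    #: ordered (class_id, onset_ms, offset_ms) tiling [0, window_ms)
    schedule: tuple = ((0, 0.0, 500.0), (1, 500.0, 2000.0), (2, 2000.0, 3500.0))
    #: (low Hz, high Hz, relative power) carriers for the amplitude envelope
    carrier_bands: tuple = ((8.0, 14.0, 1.0), (14.0, 20.0, 0.5))
    snr: float = 2.0            # signal/noise RMS amplitude ratio; inf = clean
    amplitude_scale: float = 1.0
    n_trials: int = 1
    seed: int = 0
    carrier_seed: int | None = None   # shared across conditions when set

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        top = max(b[1] for b in self.carrier_bands)
        if self.sampling_rate <= 2 * top:
            raise ValueError("sampling_rate must exceed twice the highest carrier edge")
        _validate_schedule(self.schedule, self.window_ms)

    @property
    def n_samples(self) -> int:
        # 3500 ms at 125 Hz is 437.5 periods -> 438 samples
        return int(np.floor(self.window_ms * self.sampling_rate / 1000.0 + 0.5))


def _validate_schedule(schedule, window_ms) -> None:
    if not schedule:
        raise ValueError("empty schedule")
    prev_off = 0.0
    for class_id, on, off in schedule:
        if on != prev_off:
            raise ValueError(f"schedule segments must tile [0, window): gap/overlap at {on}")
        if off <= on:
            raise ValueError("segment offset must exceed onset")
        prev_off = off
    if prev_off != window_ms:
        raise ValueError("schedule must end at window_ms")


@dataclass
class SimRecording:
    """One synthetic trial with its ground truth."""

    data: np.ndarray              # (n_channels, n_samples), µV
    truth_labels: np.ndarray      # (n_samples,) planted class per sample
    truth_templates: SimTemplateSet
    condition: str
    sampling_rate: float
    seed: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def make_templates(n_classes: int, n_channels: int, max_abs_corr: float = 0.5,
                   seed: int = 0, max_tries: int = 5000) -> SimTemplateSet:
    """Draw random zero-mean, unit-GFP topographies with bounded pairwise
    spatial correlation.

    Templates are added one at a time by rejection sampling; a draw is kept
    only if its absolute spatial (Pearson) correlation with every template
    already accepted stays at or below ``max_abs_corr``.  Raises if the
    ceiling is infeasible within ``max_tries`` draws (e.g. 2-channel maps,
    which are all collinear after mean removal).
    """
    if n_classes < 1 or n_channels < 2:
        raise ValueError("need n_classes >= 1 and n_channels >= 2")
    if not 0.0 < max_abs_corr < 1.0:
        raise ValueError("max_abs_corr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    tries = 0
    while len(rows) < n_classes:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not draw {n_classes} maps in {n_channels} channels with "
                f"|corr| <= {max_abs_corr} within {max_tries} draws")
        tries += 1
        v = rng.standard_normal(n_channels)
        v -= v.mean()
        g = v.std(ddof=0)
        if g < 1e-12:
            continue
        v /= g
        if all(abs(float(v @ r) / n_channels) <= max_abs_corr for r in rows):
            rows.append(v)
    return SimTemplateSet(maps=np.array(rows))


def schedule_to_labels(schedule, sampling_rate: float, window_ms: float) -> np.ndarray:
    """Sample the schedule onto the time grid.

    Sample n (at n/rate seconds) belongs to the half-open segment containing
    it; interior boundaries map to indices via floor(onset × rate / 1000).
    """
    n = int(np.floor(window_ms * sampling_rate / 1000.0 + 0.5))
    labels = np.empty(n, dtype=int)
    for class_id, on, off in schedule:
        i0 = int(np.floor(on * sampling_rate / 1000.0))
        i1 = int(np.floor(off * sampling_rate / 1000.0)) if off < window_ms else n
        labels[i0:i1] = class_id
    return labels


def _carrier(plan: SimPlan, rng: np.random.Generator,
             n_components: int = 8) -> np.ndarray:
    """Signed sum of band-limited sinusoid mixtures (mu/beta by default).

    The signed carrier multiplies the active template directly, so the
    recorded signal genuinely oscillates in the configured bands (its
    instantaneous polarity flips at the carrier rate, the classic reason
    microstate analysis is polarity-invariant), while GFP follows the
    rectified envelope |carrier| and therefore peaks throughout every
    planted segment.  Normalized so the mean of |carrier| is 1, making
    ``amplitude_scale`` the mean noiseless GFP.
    """
    t = np.arange(plan.n_samples) / plan.sampling_rate
    carrier = np.zeros_like(t)
    for low, high, w in plan.carrier_bands:
        freqs = rng.uniform(low, high, n_components)
        phases = rng.uniform(0, 2 * np.pi, n_components)
        band = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        carrier += w * band.sum(axis=0) / np.sqrt(n_components)
    return carrier / np.abs(carrier).mean()


def synthesize_recording(templates: SimTemplateSet, plan: SimPlan,
                         condition: str = "sim") -> SimRecording:
    """Build one trial: data(t) = scale × carrier(t) × template[label(t)] + noise.

    Noise is white Gaussian across channels and time, scaled so the
    RMS-amplitude ratio of the noiseless signal to the noise equals
    ``plan.snr``.  The carrier phases derive from ``plan.carrier_seed``
    (defaulting to ``plan.seed``) so two conditions can share a carrier
    while drawing independent noise.
    """
    labels = schedule_to_labels(plan.schedule, plan.sampling_rate, plan.window_ms)
    if labels.max() >= templates.n_classes:
        raise ValueError("schedule class id out of range for template set")
    carrier_seed = plan.seed if plan.carrier_seed is None else plan.carrier_seed
    env = _carrier(plan, np.random.default_rng([carrier_seed, 11]))
    clean = plan.amplitude_scale * env[None, :] * templates.maps[labels].T
    if np.isfinite(plan.snr):
        rng = np.random.default_rng([plan.seed, 13])
        sigma = float(np.sqrt(np.mean(clean ** 2))) / plan.snr
        data = clean + rng.standard_normal(clean.shape) * sigma
    else:
        data = clean
    return SimRecording(data=data, truth_labels=labels,
                        truth_templates=templates, condition=condition,
                        sampling_rate=plan.sampling_rate, seed=plan.seed)


def default_conditions(window_ms: float = 3500.0):
    """The six hand-grip conditions: {executed, imagined} × {4, 10, 16} kg.

    Amplitude scales follow the measured mean-GFP presets; the planted
    schedule is A for the 0–500 ms preparation period, then B, then C with
    the B→C boundary moving earlier as the force target rises.
    """
    conditions = {}
    for mode in ("executed", "imagined"):
        for force in (4, 10, 16):
            name = f"{mode}_{force}kg"
            b_dur = B_DURATION_PRESETS[(mode, force)]
            schedule = (
                (0, 0.0, 500.0),
                (1, 500.0, 500.0 + b_dur),
                (2, 500.0 + b_dur, window_ms),
            )
            conditions[name] = {
                "amplitude_scale": AMPLITUDE_PRESETS[(mode, force)],
                "schedule": schedule,
                "mode": mode,
                "force_kg": force,
            }
    return conditions


@dataclass
class StudyConfig:
    """Configuration of a full synthetic study (6 conditions × n_trials)."""

    n_classes: int = 3
    n_channels: int = 9
    sampling_rate: float = 125.0
    window_ms: float = 3500.0
    n_trials: int = 1
    snr: float = 2.0
    carrier_bands: tuple = ((8.0, 14.0, 1.0), (14.0, 20.0, 0.5))
    max_abs_corr: float = 0.5
    #: multiplicative log-normal jitter of per-condition amplitude (SD of the
    #: log); emulates between-recording gain variability
    amplitude_jitter_sd: float = 0.0
    seed: int = 0
    conditions: dict | None = None    # name -> {amplitude_scale, schedule, ...}

    def resolved_conditions(self) -> dict:
        return self.conditions if self.conditions is not None \
            else default_conditions(self.window_ms)


@dataclass
class SimStudy:
    templates: SimTemplateSet
    recordings: list
    config: StudyConfig

    def by_condition(self) -> dict:
        out: dict[str, list] = {}
        for rec in self.recordings:
            out.setdefault(rec.condition, []).append(rec)
        return out


def simulate_study(config: StudyConfig,
                   templates: SimTemplateSet | None = None) -> SimStudy:
    """Generate n_trials recordings for each configured condition.

    All conditions share one planted template set (pass ``templates`` to
    share it across several studies, e.g. one study per subject).  The
    envelope carrier seed is shared across conditions within a trial index
    (so amplitude contrasts between conditions are exactly the configured
    scale ratios in the noiseless limit), while noise seeds are independent
    per condition × trial.
    """
    cfg = config
    if templates is None:
        templates = make_templates(cfg.n_classes, cfg.n_channels,
                                   cfg.max_abs_corr, seed=[cfg.seed, 5])
    jitter_rng = np.random.default_rng([cfg.seed, 17])
    recordings = []
    for ci, (name, spec) in enumerate(sorted(cfg.resolved_conditions().items())):
        scale = spec["amplitude_scale"]
        if cfg.amplitude_jitter_sd > 0:
            scale = scale * float(np.exp(jitter_rng.normal(0.0, cfg.amplitude_jitter_sd)))
        for trial in range(cfg.n_trials):
            plan = SimPlan(
                sampling_rate=cfg.sampling_rate,
                window_ms=cfg.window_ms,
                schedule=tuple(tuple(seg) for seg in spec["schedule"]),
                carrier_bands=cfg.carrier_bands,
                snr=cfg.snr,
                amplitude_scale=scale,
                n_trials=1,
                seed=_mix(cfg.seed, 101, ci, trial),
                carrier_seed=_mix(cfg.seed, 103, trial),
            )
            recordings.append(synthesize_recording(templates, plan, condition=name))
    return SimStudy(templates=templates, recordings=recordings, config=cfg)


def _mix(*keys) -> int:
    """Stable small-integer seed derived from a tuple of integers."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def write_study(study: SimStudy, outdir) -> None:
    """Write one delimited channels×time matrix per trial, an events table,
    and a JSON sidecar with the ground truth (labels, templates, config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [f"ch{i}" for i in range(study.templates.n_channels)]
    events = []
    sidecar: dict = {
        "templates": study.templates.maps.tolist(),
        "sampling_rate": study.config.sampling_rate,
        "window_ms": study.config.window_ms,
        "seed": study.config.seed,
        "trials": {},
    }
    counters: dict[str, int] = {}
    for rec in study.recordings:
        trial = counters.get(rec.condition, 0)
        counters[rec.condition] = trial + 1
        stem = f"{rec.condition}_trial{trial:02d}"
        with open(outdir / f"{stem}.csv", "w") as fh:
            fh.write(",".join(names) + "\n")
            for row in rec.data:
                fh.write(",".join(f"{x:.6g}" for x in row) + "\n")
        events.append((0, rec.condition, stem))
        sidecar["trials"][stem] = {
            "condition": rec.condition,
            "seed": rec.seed,
            "truth_labels": rec.truth_labels.tolist(),
        }
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("onset_sample\tcondition\ttrial_id\n")
        for onset, cond, tid in events:
            fh.write(f"{onset}\t{cond}\t{tid}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
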
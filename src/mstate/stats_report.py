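"""Condition-level statistics and pipeline orchestration.

The study design crosses grip-force mode (executed, imagined) with force
target (4, 10, 16 kg).  Each microstate parameter is analyzed with a 2×3
two-factor ANOVA (main effects only, type-II sums of squares, subjects as
observations) and with nine pairwise comparison groups:

    #1 imagined 4 vs 10 kg     #4 executed 4 vs 10 kg   #7 imagined vs executed 4 kg
    #2 imagined 4 vs 16 kg     #5 executed 4 vs 16 kg   #8 imagined vs executed 10 kg
    #3 imagined 10 vs 16 kg    #6 executed 10 vs 16 kg  #9 imagined vs executed 16 kg

Pairwise comparisons are one-way F tests; uncorrected p-values are
reported at the 0.05 level alongside a Holm-adjusted column.

``run_pipeline`` drives the whole chain — simulation (or file input),
GFP/peak extraction, clustering with class-count selection, backfitting,
parameter estimation, syntax, band correlation, and these statistics —
and writes delimited tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .gfp import compute_gfp, find_gfp_peaks, concatenate_peaks
from .io_preprocess import Recording
from . import cluster as _cluster
from . import segment as _segment
from .params import microstate_parameters
from .bandcorr import microstate_band_correlogram, default_bands
from .synth import StudyConfig, simulate_study, _mix

__all__ = ["ComparisonSpec", "COMPARISON_GROUPS", "anova_two_factor",
           "pairwise_comparisons", "run_pipeline"]


@dataclass(frozen=True)
class ComparisonSpec:
    group_id: int
    left: str
    right: str


COMPARISON_GROUPS = (
    ComparisonSpec(1, "imagined_4kg", "imagined_10kg"),
    ComparisonSpec(2, "imagined_4kg", "imagined_16kg"),
    ComparisonSpec(3, "imagined_10kg", "imagined_16kg"),
    ComparisonSpec(4, "executed_4kg", "executed_10kg"),
    ComparisonSpec(5, "executed_4kg", "executed_16kg"),
    ComparisonSpec(6, "executed_10kg", "executed_16kg"),
    ComparisonSpec(7, "imagined_4kg", "executed_4kg"),
    ComparisonSpec(8, "imagined_10kg", "executed_10kg"),
    ComparisonSpec(9, "imagined_16kg", "executed_16kg"),
)


def _split_condition(cond: str) -> tuple[str, str]:
    mode, force = cond.split("_", 1)
    return mode, force


def anova_two_factor(df: pd.DataFrame, parameter: str,
                     class_label) -> pd.DataFrame:
    """Main-effect F/p for mode (2 levels) and force (3 levels).

    ``df`` is a long table with columns subject, condition, class,
    parameter, value; subject means are the observations.  No interaction
    term is fitted; sums of squares are type II, so unbalanced designs are
    handled.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = df[(df["parameter"] == parameter) & (df["class"] == class_label)].copy()
    if sub.empty:
        raise ValueError(f"no rows for parameter={parameter}, class={class_label}")
    sub["mode"], sub["force"] = zip(*sub["condition"].map(_split_condition))
    counts = sub.groupby(["mode", "force"])["value"].count()
    if (counts < 2).any():
        raise ValueError("fewer than 2 observations in some design cell")
    model = smf.ols("value ~ C(mode) + C(force)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rows = []
    for effect, label in (("C(mode)", "mode"), ("C(force)", "force")):
        rows.append({"parameter": parameter, "class": class_label,
                     "group": label, "F": float(table.loc[effect, "F"]),
                     "p": float(table.loc[effect, "PR(>F)"])})
    return pd.DataFrame(rows)


def pairwise_comparisons(df: pd.DataFrame, parameter: str,
                         class_label) -> pd.DataFrame:
    """One-way F tests for the nine comparison groups, with Holm adjustment."""
    from statsmodels.stats.multitest import multipletests

    sub = df[(df["parameter"] == parameter) & (df["class"] == class_label)]
    rows = []
    for spec in COMPARISON_GROUPS:
        a = sub.loc[sub["condition"] == spec.left, "value"].to_numpy()
        b = sub.loc[sub["condition"] == spec.right, "value"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(f"group #{spec.group_id}: fewer than 2 subjects per side")
        if np.allclose(a.var(ddof=0) + b.var(ddof=0), 0) and np.allclose(a.mean(), b.mean()):
            F, p = 0.0, 1.0
        else:
            F, p = sps.f_oneway(a, b)
        rows.append({"parameter": parameter, "class": class_label,
                     "group": f"#{spec.group_id}", "left": spec.left,
                     "right": spec.right, "F": float(F), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


def pooled_study_peaks(seed: int, n_trials: int = 4, avg_group: int = 2,
                       snr: float = 2.0, flank: int = 4, n_classes: int = 3,
                       n_channels: int = 9):
    """GFP-peak pool of one synthetic study, following the preprocessing
    chain's trial-averaging stage.

    Trials of each condition are averaged in groups of ``avg_group``
    (session averages); GFP peaks of every averaged recording are pooled
    with the condition as stratum.  Returns ``(peaks, study)``.
    """
    cfg = StudyConfig(seed=seed, n_trials=n_trials, snr=snr,
                      n_classes=n_classes, n_channels=n_channels)
    study = simulate_study(cfg)
    sets, strata = [], []
    for cond, recs in sorted(study.by_condition().items()):
        for gi in range(0, len(recs), avg_group):
            chunk = recs[gi:gi + avg_group]
            mean = np.mean([r.data for r in chunk], axis=0)
            rec = Recording(data=mean, sampling_rate=cfg.sampling_rate,
                            reference="common_average")
            g = compute_gfp(rec)
            sets.append(find_gfp_peaks(g, rec, flank=flank))
            strata.append(cond)
    return concatenate_peaks(sets, strata=strata), study


def recover_class_count(study_seed: int, rng_seed: int | None = None,
                        k_range=range(1, 7), n_reps: int = 100,
                        train_frac: float = 0.8):
    """Full class-count recovery on one synthetic study.

    Generates the study, pools its GFP peaks, runs the repeated 80/20
    cross-validation and the pseudo-statistic curves, and returns the
    ``KSelection`` together with the peak pool.
    """
    rng_seed = study_seed if rng_seed is None else rng_seed
    peaks, _ = pooled_study_peaks(study_seed)
    cv = _cluster.cross_validate_k(peaks, k_range=k_range, n_reps=n_reps,
                                   train_frac=train_frac, seed=rng_seed)
    curves = _cluster.pseudo_stat_curves(
        peaks, k_range=[k for k in k_range if k >= 2], seed=rng_seed)
    return _cluster.select_k(cv, curves), peaks


# ----------------------------------------------------------------- pipeline

DEFAULT_CONFIG = {
    "simulate": {"n_subjects": 4, "n_trials": 2, "snr": 2.0, "n_channels": 9,
                 "n_classes": 3, "sampling_rate": 125.0, "window_ms": 3500.0,
                 "amplitude_jitter_sd": 0.1},
    "gfp": {"flank": 4},
    "cluster": {"k_range": [1, 2, 3, 4, 5, 6], "n_reps": 100,
                "train_frac": 0.8, "n_restarts": 2,
                "polarity_mode": "invariant"},
    "segment": {"mode": "nearest_peak", "min_duration_ms": 0.0},
    "params": {"amp_denominator": "peak_count"},
    "bandcorr": {"smooth_ms": 250.0, "literal_theta": False},
}


def _merge_config(user: dict | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for block, values in (user or {}).items():
        cfg.setdefault(block, {}).update(values or {})
    return cfg


def run_pipeline(config: dict | None = None, seed: int = 0,
                 outdir=None) -> dict:
    """Execute the full microstate analysis on a simulated study.

    Returns a bundle of result tables; when ``outdir`` is given, every
    table is also written as CSV together with a JSON manifest recording
    the configuration, seeds and decisions taken (selected class count,
    class-name mapping, stage notes).
    """
    cfg = _merge_config(config)
    sim = cfg["simulate"]
    flank = int(cfg["gfp"]["flank"])
    stage = "simulate"
    try:
        # --- simulate one study per subject, all sharing the planted
        #     template set (subjects differ in noise and gain jitter) ------
        from .synth import make_templates
        shared_templates = make_templates(int(sim["n_classes"]),
                                          int(sim["n_channels"]),
                                          seed=[seed, 5])
        subjects = []
        for s in range(int(sim["n_subjects"])):
            study_cfg = StudyConfig(
                n_classes=int(sim["n_classes"]), n_channels=int(sim["n_channels"]),
                sampling_rate=float(sim["sampling_rate"]),
                window_ms=float(sim["window_ms"]), n_trials=int(sim["n_trials"]),
                snr=float(sim["snr"]),
                amplitude_jitter_sd=float(sim["amplitude_jitter_sd"]),
                seed=_mix(seed, 211, s))
            subjects.append(simulate_study(study_cfg, templates=shared_templates))

        # --- per subject × condition averages, GFP, peaks ---------------
        stage = "gfp/peaks"
        averages: dict[tuple, Recording] = {}
        gfps, peaksets, strata = {}, {}, []
        peaks_list = []
        for s, study in enumerate(subjects):
            for cond, recs in sorted(study.by_condition().items()):
                mean = np.mean([r.data for r in recs], axis=0)
                rec = Recording(data=mean, sampling_rate=study.config.sampling_rate,
                                reference="common_average")
                key = (s, cond)
                averages[key] = rec
                g = compute_gfp(rec)
                gfps[key] = g
                p = find_gfp_peaks(g, rec, flank=flank)
                peaksets[key] = p
                peaks_list.append(p)
                strata.append(cond)
        pooled = concatenate_peaks(peaks_list, strata=strata)

        # --- clustering and class-count selection ------------------------
        stage = "cluster"
        cl = cfg["cluster"]
        k_range = list(cl["k_range"])
        cv = _cluster.cross_validate_k(
            pooled, k_range=k_range, n_reps=int(cl["n_reps"]),
            train_frac=float(cl["train_frac"]), seed=_mix(seed, 223),
            n_restarts=int(cl["n_restarts"]), polarity_mode=cl["polarity_mode"])
        curves = _cluster.pseudo_stat_curves(
            pooled, k_range=[k for k in k_range if k >= 2],
            seed=_mix(seed, 227), polarity_mode=cl["polarity_mode"])
        selection = _cluster.select_k(cv, curves)
        templates, partition = _cluster.kmeans_microstates(
            pooled, selection.k, n_restarts=10, seed=_mix(seed, 229),
            polarity_mode=cl["polarity_mode"])
        gev = _cluster.explained_variance(pooled, templates)

        # --- backfitting, naming, parameters, syntax, band correlation ---
        stage = "segment/params/bandcorr"
        sg, pr, bc = cfg["segment"], cfg["params"], cfg["bandcorr"]
        bands = default_bands(literal_theta=bool(bc["literal_theta"]))
        label_series = {}
        for (s, cond), rec in averages.items():
            g, p = gfps[(s, cond)], peaksets[(s, cond)]
            ls = _segment.backfit(rec, g, p, templates, mode=sg["mode"])
            label_series[(s, cond)] = _segment.smooth_runs(
                ls, float(sg["min_duration_ms"]), rec, templates)
        # class letters by first temporal occurrence, scanned over all
        # backfitted recordings so every class gets a name
        all_labels = np.concatenate(
            [label_series[k].labels for k in sorted(label_series)])
        names = _segment.first_occurrence_names(
            _segment.LabelSeries(labels=all_labels, sampling_rate=1000.0))
        param_rows, corr_rows, gfp_rows, syntax_rows = [], [], [], []
        for (s, cond), rec in averages.items():
            g, p = gfps[(s, cond)], peaksets[(s, cond)]
            ls = label_series[(s, cond)]
            peak_labels = _segment.peak_class_labels(p, templates)
            ptab = microstate_parameters(
                ls, g, p, peak_labels, wt_ms=float(sim["window_ms"]),
                amp_denominator=pr["amp_denominator"], class_names=names,
                n_classes=templates.k)
            for _, row in ptab.iterrows():
                for parameter in ("duration_ms", "occurrence_count",
                                  "occurrence_per_s", "time_coverage_pct",
                                  "amplitude_uV"):
                    param_rows.append({"subject": s, "condition": cond,
                                       "class": row["class"],
                                       "parameter": parameter,
                                       "value": row[parameter]})
            syn = _segment.extract_syntax(ls)
            syntax_rows.append({"subject": s, "condition": cond,
                                "sequence": "".join(names.get(c, str(c))
                                                    for c in syn.sequence)})
            ctab = microstate_band_correlogram(ls, g, rec, bands=bands,
                                               smooth_ms=float(bc["smooth_ms"]),
                                               class_names=names)
            ctab.insert(0, "condition", cond)
            ctab.insert(0, "subject", s)
            corr_rows.append(ctab)
            gfp_rows.append({"subject": s, "condition": cond,
                             "mean_gfp_uV": float(g.values.mean())})

        params_long = pd.DataFrame(param_rows)
        correlogram = pd.concat(corr_rows, ignore_index=True)
        gfp_table = pd.DataFrame(gfp_rows)
        syntax_table = pd.DataFrame(syntax_rows)

        # --- statistics ---------------------------------------------------
        stage = "stats"
        anova_rows, pairwise_rows = [], []
        class_labels = sorted(params_long["class"].unique())
        for parameter in ("duration_ms", "occurrence_count",
                          "time_coverage_pct", "amplitude_uV"):
            for cls in class_labels:
                anova_rows.append(anova_two_factor(params_long, parameter, cls))
                pairwise_rows.append(pairwise_comparisons(params_long, parameter, cls))
        anova_table = pd.concat(anova_rows, ignore_index=True)
        pairwise_table = pd.concat(pairwise_rows, ignore_index=True)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    cv_table = pd.DataFrame({"k": cv.k_values, "mean_corr": cv.mean_corr})
    table1 = (gfp_table.groupby("condition")["mean_gfp_uV"]
              .agg(["mean", "std"]).reset_index())
    table2 = (params_long.groupby(["condition", "class", "parameter"])["value"]
              .agg(["mean", "std"]).reset_index())

    bundle = {
        "selected_k": selection.k,
        "selection": selection,
        "gev_pct": gev,
        "class_names": names,
        "cv_curve": cv_table,
        "pseudo_curves": curves,
        "templates": templates.to_frame(),
        "gfp_by_condition": table1,
        "params_long": params_long,
        "params_summary": table2,
        "syntax": syntax_table,
        "correlogram": correlogram,
        "anova": anova_table,
        "pairwise": pairwise_table,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("cv_curve", "pseudo_curves", "templates",
                     "gfp_by_condition", "params_long", "params_summary",
                     "syntax", "correlogram", "anova", "pairwise"):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "package_version": __version__,
            "seed": seed,
            "config": cfg,
            "selected_k": selection.k,
            "selection": {"cv_k": selection.cv_k,
                          "pseudo_f_k": selection.pseudo_f_k,
                          "pseudo_t2_k": selection.pseudo_t2_k,
                          "agree": selection.agree, "note": selection.note},
            "gev_pct": gev,
            "class_names": {str(k): v for k, v in (names or {}).items()},
            "outputs": [f"{n}.csv" for n in
                        ("cv_curve", "pseudo_curves", "templates",
                         "gfp_by_condition", "params_long", "params_summary",
                         "syntax", "correlogram", "anova", "pairwise")],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return bundle
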
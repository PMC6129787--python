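"""Microstate clustering of GFP-peak topographies.

Peak maps are clustered with a modified k-means that measures similarity
by the spatial Pearson correlation between maps (polarity-invariant by
default, the classic microstate convention): assignment picks the template
with maximal |correlation|, and the update step replaces each template by
the first principal direction of its assigned maps (polarity-invariant
mode) or their normalized mean (signed mode).

The number of classes is selected by combining
  * repeated 80/20 cross-validation: templates fitted on the training
    peaks are scored by the mean maximal correlation attained on held-out
    peaks, averaged over (by default) 100 random splits, with a parsimony
    tie-break, and
  * pseudo-F (Calinski–Harabasz style) and pseudo-t² (Duda–Hart style)
    scatter statistics computed on the unit-GFP-normalized peak maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gfp import PeakSet

__all__ = [
    "TemplateSet", "PeakPartition", "CVResult", "KSelection",
    "spatial_correlation", "kmeans_microstates", "cross_validate_k",
    "pseudo_F", "pseudo_t2", "pseudo_stat_curves", "select_k",
    "explained_variance",
]


@dataclass
class TemplateSet:
    """Microstate class topographies (zero channel-mean, unit GFP rows)."""

    maps: np.ndarray                       # (k, n_channels)
    labels: list = field(default_factory=list)   # class names, e.g. A, B, C
    polarity_mode: str = "invariant"       # or "signed"

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not self.labels:
            self.labels = [str(i) for i in range(self.maps.shape[0])]
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per template row required")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def to_frame(self, channel_names=None) -> pd.DataFrame:
        names = channel_names or [f"ch{i}" for i in range(self.n_channels)]
        df = pd.DataFrame(self.maps, columns=list(names))
        df.insert(0, "class", self.labels)
        return df


@dataclass
class PeakPartition:
    """A partition of peak maps with its scatter decomposition.

    Scatter quantities are computed on unit-GFP-normalized maps (sign-aligned
    to their assigned template in polarity-invariant mode) so amplitude
    differences between conditions do not drive the cluster-number
    statistics.
    """

    assignments: np.ndarray     # class id per peak
    k: int
    within_ss: np.ndarray       # W_p per class
    total_ss: float             # T
    n_p: np.ndarray             # per-class counts
    points: np.ndarray          # the (aligned) points the scatter refers to

    @property
    def n(self) -> int:
        return int(self.assignments.size)

    @property
    def pooled_within(self) -> float:
        return float(self.within_ss.sum())

    @classmethod
    def from_points(cls, points: np.ndarray, assignments: np.ndarray,
                    k: int | None = None) -> "PeakPartition":
        """Scatter decomposition of arbitrary points (rows) under a labeling.

        Works for 1-D data as well (used by the hand-computable oracles).
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        a = np.asarray(assignments, dtype=int)
        k = int(a.max()) + 1 if k is None else k
        grand = pts.mean(axis=0)
        total = float(((pts - grand) ** 2).sum())
        within = np.zeros(k)
        counts = np.zeros(k, dtype=int)
        for c in range(k):
            sub = pts[a == c]
            counts[c] = sub.shape[0]
            if sub.shape[0] > 0:
                within[c] = float(((sub - sub.mean(axis=0)) ** 2).sum())
        return cls(assignments=a, k=k, within_ss=within, total_ss=total,
                   n_p=counts, points=pts)


@dataclass
class CVResult:
    """Cross-validation curve over candidate class counts."""

    k_values: np.ndarray
    mean_corr: np.ndarray          # averaged over repetitions, per k
    per_rep_corr: np.ndarray       # (n_reps, len(k_values))
    n_reps: int
    train_frac: float
    seed: int


@dataclass
class KSelection:
    """Outcome of the cluster-number selection."""

    k: int
    cv_k: int | None               # None when the CV curve is flat
    pseudo_f_k: int | None
    pseudo_t2_k: int | None
    agree: bool
    note: str = ""

    @property
    def pseudo_k(self) -> int | None:
        """Joint pseudo-statistic indication (pseudo-F primary)."""
        return self.pseudo_f_k if self.pseudo_f_k is not None else self.pseudo_t2_k


# ------------------------------------------------------------ similarity

def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Remove channel means and scale rows to unit GFP (unit spatial SD)."""
    m = np.atleast_2d(np.asarray(maps, dtype=float))
    m = m - m.mean(axis=1, keepdims=True)
    g = m.std(axis=1, ddof=0)
    if np.any(g < 1e-12):
        raise ValueError("zero-variance map cannot be normalized")
    return m / g[:, None]


def spatial_correlation(map1, map2, polarity_mode: str = "invariant") -> float:
    """Pearson correlation across channels of two mean-removed maps;
    absolute value in polarity-invariant mode."""
    a = np.asarray(map1, dtype=float)
    b = np.asarray(map2, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = a.std(ddof=0), b.std(ddof=0)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-variance map")
    r = float(a @ b / (a.size * na * nb))
    return abs(r) if polarity_mode == "invariant" else r


def _corr_matrix(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pairwise spatial correlations, rows of X vs rows of T (both normalized)."""
    return X @ T.T / X.shape[1]


# --------------------------------------------------------------- k-means

def _update_template(sub: np.ndarray, polarity_mode: str) -> np.ndarray:
    if polarity_mode == "invariant":
        # first principal direction of the assigned maps
        cov = sub.T @ sub
        _, vecs = np.linalg.eigh(cov)
        t = vecs[:, -1]
    else:
        t = sub.mean(axis=0)
        if np.linalg.norm(t) < 1e-12:
            t = sub[0]
    return normalize_maps(t[None, :])[0]


def kmeans_microstates(peaks: PeakSet | np.ndarray, k: int,
                       n_restarts: int = 10, seed: int = 0,
                       polarity_mode: str = "invariant",
                       max_iter: int = 500):
    """Modified k-means on peak topographies.

    Alternates assignment (maximal spatial correlation, absolute in
    polarity-invariant mode) and template update (first principal direction
    of the assigned maps, or their normalized mean in signed mode) until
    the assignment stabilizes or ``max_iter`` is reached.  The best of
    ``n_restarts`` random initializations by total explained similarity is
    returned.  Deterministic given ``seed``.

    Returns ``(TemplateSet, PeakPartition)``.
    """
    raw = peaks.maps if isinstance(peaks, PeakSet) else np.asarray(peaks)
    X = normalize_maps(raw)
    n, c = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of peaks ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        T = X[rng.choice(n, size=k, replace=False)].copy()
        assign = np.full(n, -1)
        for _ in range(max_iter):
            C = _corr_matrix(X, T)
            S = np.abs(C) if polarity_mode == "invariant" else C
            new_assign = S.argmax(axis=1)
            # re-seed empty clusters from the worst-fitted map
            fit = S[np.arange(n), new_assign]
            for c_id in range(k):
                if not np.any(new_assign == c_id):
                    worst = int(np.argmin(fit))
                    new_assign[worst] = c_id
                    fit[worst] = np.inf
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c_id in range(k):
                sub = X[assign == c_id]
                T[c_id] = _update_template(sub, polarity_mode)
        C = _corr_matrix(X, T)
        S = np.abs(C) if polarity_mode == "invariant" else C
        fit = S[np.arange(n), assign]
        objective = float((fit ** 2).sum()) if polarity_mode == "invariant" \
            else float(fit.sum())
        if best is None or objective > best[0]:
            best = (objective, T.copy(), assign.copy())
    _, T, assign = best
    if polarity_mode == "invariant":
        signs = np.sign(_corr_matrix(X, T)[np.arange(n), assign])
        signs[signs == 0] = 1.0
        aligned = X * signs[:, None]
    else:
        aligned = X
    partition = PeakPartition.from_points(aligned, assign, k=k)
    templates = TemplateSet(maps=T, polarity_mode=polarity_mode)
    return templates, partition


def kmeans_objective(maps: np.ndarray, templates: TemplateSet) -> float:
    """Total explained similarity of maps under a template set."""
    X = normalize_maps(maps)
    C = _corr_matrix(X, normalize_maps(templates.maps))
    if templates.polarity_mode == "invariant":
        return float((np.abs(C).max(axis=1) ** 2).sum())
    return float(C.max(axis=1).sum())


# ------------------------------------------------------ pseudo statistics

def pseudo_F(partition: PeakPartition) -> float:
    """Calinski–Harabasz-style statistic ((T−P_k)/(k−1)) / (P_k/(n−k)).

    Degenerate cases: 0 when there is no scatter at all (T = 0); +inf when
    the partition is perfect (P_k = 0 with T > 0).
    """
    k, n = partition.k, partition.n
    if k < 2:
        raise ValueError("pseudo_F requires k >= 2")
    if n <= k:
        raise ValueError("pseudo_F requires n > k")
    T = partition.total_ss
    P = partition.pooled_within
    if T <= 0:
        return 0.0
    if P <= 0:
        return float("inf")
    return ((T - P) / (k - 1)) / (P / (n - k))


def _within_ss(points: np.ndarray) -> float:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        return 0.0
    return float(((pts - pts.mean(axis=0)) ** 2).sum())


def pseudo_t2(class_p: np.ndarray, class_q: np.ndarray) -> float:
    """Duda–Hart-style merge statistic for two clusters of points.

    B²pq = W_merged − W_p − W_q (the scatter increase caused by merging),
    t² = B²pq / ((W_p + W_q) / (n_p + n_q − 2)).  A large value means the
    two clusters are genuinely distinct.  Degenerate denominator: +inf when
    B² > 0, else 0.
    """
    p = np.asarray(class_p, dtype=float)
    q = np.asarray(class_q, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if q.ndim == 1:
        q = q[:, None]
    n_p, n_q = p.shape[0], q.shape[0]
    if n_p + n_q <= 2:
        raise ValueError("pseudo_t2 requires n_p + n_q > 2")
    Wp, Wq = _within_ss(p), _within_ss(q)
    B2 = _within_ss(np.vstack([p, q])) - Wp - Wq
    denom = (Wp + Wq) / (n_p + n_q - 2)
    if denom <= 0:
        return float("inf") if B2 > 0 else 0.0
    return float(B2 / denom)


def merge_candidates(partition: PeakPartition):
    """The cluster pair whose merge minimally increases pooled within-class
    scatter (Ward-style), with the pseudo-t² of that merge."""
    pts, a = partition.points, partition.assignments
    best = None
    for p in range(partition.k):
        for q in range(p + 1, partition.k):
            if partition.n_p[p] == 0 or partition.n_p[q] == 0:
                continue
            delta = _within_ss(pts[(a == p) | (a == q)]) \
                - partition.within_ss[p] - partition.within_ss[q]
            if best is None or delta < best[0]:
                best = (delta, p, q)
    if best is None:
        raise ValueError("partition has fewer than two non-empty clusters")
    _, p, q = best
    return (p, q), pseudo_t2(pts[a == p], pts[a == q])


def pseudo_stat_curves(peaks: PeakSet | np.ndarray, k_range=range(2, 7),
                       seed: int = 0, n_restarts: int = 10,
                       polarity_mode: str = "invariant") -> pd.DataFrame:
    """Pseudo-F and pseudo-t² as functions of the class count.

    For each k a fresh k-means fit provides the partition; pseudo-t²(k)
    scores the merge that would take the k-class solution to k−1 classes.
    """
    rows = []
    for i, k in enumerate(k_range):
        if k < 2:
            continue
        _, part = kmeans_microstates(peaks, k, n_restarts=n_restarts,
                                     seed=seed + 7919 * i,
                                     polarity_mode=polarity_mode)
        f = pseudo_F(part)
        _, t2 = merge_candidates(part)
        rows.append({"k": k, "pseudo_F": f, "pseudo_t2": t2})
    return pd.DataFrame(rows)


# -------------------------------------------------------- cross-validation

def _stratified_split(strata: np.ndarray, train_frac: float,
                      rng: np.random.Generator):
    train_idx, test_idx = [], []
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        if idx.size < 2:
            raise ValueError(f"stratum {s!r} too small to split")
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def cross_validate_k(peaks: PeakSet, k_range=range(1, 7), n_reps: int = 100,
                     train_frac: float = 0.8, seed: int = 0,
                     n_restarts: int = 3,
                     polarity_mode: str = "invariant") -> CVResult:
    """Repeated stratified 80/20 cross-validation of the class count.

    Per repetition and per k: fit templates on the training peaks, then
    score the held-out peaks by the mean maximal spatial correlation to any
    fitted template.  Stratification (by ``peaks.strata``, e.g. condition)
    guarantees every stratum contributes to both sets.
    """
    X = normalize_maps(peaks.maps)
    strata = peaks.strata if peaks.strata is not None \
        else np.zeros(X.shape[0], dtype=int)
    ks = np.asarray(list(k_range), dtype=int)
    rng = np.random.default_rng(seed)
    per_rep = np.zeros((n_reps, ks.size))
    for rep in range(n_reps):
        tr, te = _stratified_split(np.asarray(strata), train_frac, rng)
        Xte = X[te]
        for j, k in enumerate(ks):
            tmpl, _ = kmeans_microstates(X[tr], int(k), n_restarts=n_restarts,
                                         seed=int(rng.integers(2 ** 31)),
                                         polarity_mode=polarity_mode)
            C = _corr_matrix(Xte, tmpl.maps)
            S = np.abs(C) if polarity_mode == "invariant" else C
            per_rep[rep, j] = float(S.max(axis=1).mean())
    return CVResult(k_values=ks, mean_corr=per_rep.mean(axis=0),
                    per_rep_corr=per_rep, n_reps=n_reps,
                    train_frac=train_frac, seed=seed)


# ------------------------------------------------------------- selection

def _pick_cv(cv: CVResult, flat_tol: float, parsimony: float) -> int | None:
    mc = cv.mean_corr
    if mc.max() - mc.min() < flat_tol:
        return None                      # flat curve: no preference
    ok = mc >= (1.0 - parsimony) * mc.max()
    return int(cv.k_values[np.nonzero(ok)[0][0]])


def _pick_local_max(ks: np.ndarray, values: np.ndarray) -> int | None:
    finite = np.isfinite(values)
    if not finite.any():
        return None
    v = np.where(finite, values, -np.inf)
    for i in range(1, v.size - 1):       # first interior local maximum
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            return int(ks[i])
    return int(ks[int(np.argmax(v))])


def _pick_t2(ks: np.ndarray, values: np.ndarray) -> int | None:
    """Change point of the pseudo-t² merge curve.

    A literal positive-to-negative sign change marks the last supported k
    directly.  Because B²pq of a pair-union merge is nonnegative, the
    collapse from cluster-scale to noise-scale values usually appears as a
    large relative drop instead of a sign flip; the k preceding the
    maximal drop (largest t²(k)/t²(k+1)) is then the last supported count.
    """
    finite = np.isfinite(values)
    if not finite.any():
        return None
    neg = np.nonzero(values < 0)[0]
    if neg.size:                         # last positive k before the sign change
        before = np.nonzero(values[:neg[0]] > 0)[0]
        if before.size:
            return int(ks[before[-1]])
    v = np.where(finite, values, np.nan)
    if v.size < 2:
        return int(ks[int(np.nanargmax(v))])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = v[:-1] / v[1:]
    if not np.isfinite(ratios).any():
        return int(ks[int(np.nanargmax(v))])
    return int(ks[int(np.nanargmax(ratios))])


def select_k(cv: CVResult, pseudo_curves: pd.DataFrame | None = None,
             flat_tol: float = 1e-3, parsimony: float = 0.01) -> KSelection:
    """Combine the CV curve with the pseudo statistics into one class count.

    The CV winner (smallest k within ``parsimony`` of the best mean test
    correlation) is authoritative; a flat CV curve expresses no preference
    and defers to the pseudo statistics.  Disagreements are recorded, not
    resolved.
    """
    if cv.k_values.size == 0:
        raise ValueError("empty k_range")
    cv_k = _pick_cv(cv, flat_tol, parsimony)
    f_k = t2_k = None
    if pseudo_curves is not None and len(pseudo_curves):
        ks = pseudo_curves["k"].to_numpy()
        f_k = _pick_local_max(ks, pseudo_curves["pseudo_F"].to_numpy(dtype=float))
        t2_k = _pick_t2(ks, pseudo_curves["pseudo_t2"].to_numpy(dtype=float))
    candidates = [x for x in (cv_k, f_k, t2_k) if x is not None]
    if not candidates:
        k = int(cv.k_values[0])
        return KSelection(k=k, cv_k=None, pseudo_f_k=None, pseudo_t2_k=None,
                          agree=True, note="no criterion expressed a preference")
    if cv_k is not None:
        k = cv_k
        note = ""
    else:
        k = f_k if f_k is not None else t2_k
        note = "flat CV curve; pseudo statistics decided"
    agree = len(set(candidates)) == 1
    if not agree:
        note = (note + "; " if note else "") + \
            f"criteria disagree (cv={cv_k}, F={f_k}, t2={t2_k})"
    return KSelection(k=int(k), cv_k=cv_k, pseudo_f_k=f_k, pseudo_t2_k=t2_k,
                      agree=agree, note=note)


# --------------------------------------------------- explained variance

def explained_variance(peaks: PeakSet, templates: TemplateSet) -> float:
    """Global explained variance (GEV) of the peak maps, in percent.

    GFP-weighted mean squared spatial correlation between each peak map and
    its best-matching template:  100 × Σ g_i² r_i² / Σ g_i².
    """
    X = normalize_maps(peaks.maps)
    C = _corr_matrix(X, normalize_maps(templates.maps))
    S = np.abs(C) if templates.polarity_mode == "invariant" else C
    r = S.max(axis=1)
    w = peaks.gfp_at_peak ** 2
    return float(100.0 * (w * r ** 2).sum() / w.sum())
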
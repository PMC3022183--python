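"""Microstate segmentation by polarity-aware topographic clustering.

Multichannel EEG/ERP topography tends to remain quasi-stable for tens of
milliseconds and then switch abruptly — the *microstate* phenomenon. The
clustering here summarizes a recording by ``q`` template maps and a
per-timeframe labeling:

* :func:`modified_kmeans` — k-means modified for topographies: the
  distance is spatial correlation, and in polarity-ignore mode (used for
  spontaneous EEG, where intrinsic oscillations flip map polarity) the
  *squared* correlation, so a map and its negation belong to one state.
  Templates are the dominant eigenvector of the members' outer-product
  sum (polarity-ignore) or their normalized mean (polarity-respect).
* :func:`aahc` — atomize-and-agglomerate hierarchical clustering: starts
  from singletons and repeatedly dissolves the cluster contributing
  least to the global explained variance, reassigning its members to
  the best-correlated survivors. Deterministic: no random
  initialization, so repeated runs give identical results.
* Model selection: :func:`cross_validation` (explained variance scaled
  by an electrode-count degrees-of-freedom penalty, lower is better)
  and :func:`kl_criterion` (Krzanowski–Lai L-corner of the dispersion
  curve).
* Temporal post-processing: :func:`smooth_labels` (fit/smoothness
  compromise), :func:`reject_small_segments`, :func:`merge_clusters`,
  :func:`sequentialize`.

The goodness-of-fit measure throughout is the **global explained
variance** (GEV): the GFP-weighted squared spatial correlation between
each map and its assigned template,

.. math:: \\mathrm{GEV} = \\frac{\\sum_t (\\mathrm{GFP}_t\\, r_t)^2}
                               {\\sum_t \\mathrm{GFP}_t^2}.

All maps are average-referenced internally; templates are unit-L2-norm,
zero-mean vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "UNASSIGNED",
    "ClusterResult",
    "DispersionCurve",
    "modified_kmeans",
    "aahc",
    "gev",
    "cross_validation",
    "kl_criterion",
    "dispersion",
    "dispersion_curve",
    "smooth_labels",
    "reject_small_segments",
    "merge_clusters",
    "sequentialize",
]

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _prepare_maps(maps, gfp_normalize: bool = False) -> np.ndarray:
    """Stack maps to (T, N), average-reference, optionally unit-GFP scale."""
    C = np.asarray(maps, dtype=float)
    if C.ndim != 2:
        raise ValueError("maps must be a T × N array (rows = timeframes)")
    C = C - C.mean(axis=1, keepdims=True)
    if gfp_normalize:
        g = np.sqrt(np.mean(C**2, axis=1, keepdims=True))
        if np.any(g <= 0):
            raise ValueError("zero-GFP map: GFP normalization undefined")
        C = C / g
    return C


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def _fix_sign(t: np.ndarray) -> np.ndarray:
    """Make the largest-|value| electrode positive (deterministic sign)."""
    i = int(np.argmax(np.abs(t)))
    return -t if t[i] < 0 else t


def _template_eig(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Dominant eigenvector and eigenvalue of a scatter matrix."""
    w, v = np.linalg.eigh(S)
    return _fix_sign(v[:, -1]), float(w[-1])


def _template_mean(members: np.ndarray) -> np.ndarray:
    m = members.mean(axis=0)
    n = np.linalg.norm(m)
    if n == 0:
        return m
    return m / n


@dataclass(frozen=True)
class ClusterResult:
    """Templates + labeling from one clustering at a fixed ``q``.

    ``templates`` is ``(q, N)`` with unit-norm, zero-mean rows; ``labels``
    holds a template index per timeframe or :data:`UNASSIGNED`; ``gev`` is
    the global explained variance; ``sigma2`` the residual variance per
    degree of freedom; ``cv`` the cross-validation score (lower better,
    NaN when ``N <= q + 1``).
    """

    templates: np.ndarray
    labels: np.ndarray
    polarity: str
    gev: float
    sigma2: float
    cv: float
    q: int

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        lab = np.asarray(self.labels, dtype=int)
        if t.ndim != 2 or t.shape[0] != self.q:
            raise ValueError("templates must be a q × N array")
        object.__setattr__(self, "templates", t)
        object.__setattr__(self, "labels", lab)


@dataclass(frozen=True)
class DispersionCurve:
    """Per-q clustering quality: within-cluster dispersion W(q), CV, GEV."""

    qs: np.ndarray
    w: np.ndarray
    n_electrodes: int
    cv: np.ndarray | None = None
    gev: np.ndarray | None = None

    def __post_init__(self) -> None:
        qs = np.asarray(self.qs, dtype=int)
        if np.any(np.diff(qs) <= 0):
            raise ValueError("q values must be strictly increasing")
        object.__setattr__(self, "qs", qs)
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))


def _finalize(C: np.ndarray, labels: np.ndarray, templates: np.ndarray,
              polarity: str) -> tuple[float, float, float]:
    """Return (gev, sigma2, cv) for a labeling."""
    T, N = C.shape
    q = templates.shape[0]
    norms2 = np.einsum("ij,ij->i", C, C)
    total = norms2.sum()
    proj = np.zeros(T)
    ok = labels >= 0
    if np.any(ok):
        proj[ok] = np.einsum("ij,ij->i", C[ok], templates[labels[ok]])
    g = float((proj**2).sum() / total) if total > 0 else 0.0
    # unassigned frames keep their full variance as residual
    resid = total - (proj**2).sum()
    sigma2 = float(resid / (T * (N - 1)))
    if N - 1 - q > 0:
        cv = sigma2 * ((N - 1) / (N - 1 - q)) ** 2
    else:
        cv = float("nan")
    return g, sigma2, cv


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

def modified_kmeans(
    maps,
    q: int,
    polarity: str = "ignore",
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-7,
    seed: int | None = None,
    gfp_normalize: bool = False,
) -> ClusterResult:
    """Polarity-aware k-means clustering of topographic maps.

    Each restart initializes templates from ``q`` distinct timeframe maps
    drawn without replacement, alternates correlation-based assignment
    with eigenvector (polarity-ignore) or normalized-mean
    (polarity-respect) template updates until the GEV improves by less
    than ``tol``, and the best restart by GEV is returned. Fully
    deterministic given ``seed``.
    """
    if polarity not in ("ignore", "respect"):
        raise ValueError("polarity must be 'ignore' or 'respect'")
    C = _prepare_maps(maps, gfp_normalize)
    T, N = C.shape
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > T:
        raise ValueError(f"q={q} exceeds number of maps T={T}")
    norms2 = np.einsum("ij,ij->i", C, C)
    total = norms2.sum()
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(T, size=q, replace=False)
        templates = _unit_rows(C[idx].copy())
        prev_gev = -np.inf
        labels = np.zeros(T, dtype=int)
        for _it in range(max_iter):
            P = C @ templates.T  # (T, q) projections
            score = P**2 if polarity == "ignore" else P
            labels = np.argmax(score, axis=1)
            # empty clusters: re-seed from the worst-fit map
            fit = score[np.arange(T), labels]
            for k in range(q):
                if not np.any(labels == k):
                    worst = int(np.argmin(fit))
                    templates[k] = _unit_rows(C[worst][None])[0]
                    labels[worst] = k
                    fit[worst] = np.inf
            for k in range(q):
                members = C[labels == k]
                if polarity == "ignore":
                    S = members.T @ members
                    templates[k], _ = _template_eig(S)
                else:
                    templates[k] = _template_mean(members)
            proj = np.einsum("ij,ij->i", C, templates[labels])
            cur_gev = (proj**2).sum() / total
            if abs(cur_gev - prev_gev) < tol:
                break
            prev_gev = cur_gev
        P = C @ templates.T
        score = P**2 if polarity == "ignore" else P
        labels = np.argmax(score, axis=1)
        proj = P[np.arange(T), labels]
        g = (proj**2).sum() / total
        if best is None or g > best[0]:
            best = (g, templates.copy(), labels.copy())

    g, templates, labels = best
    gev_v, sigma2, cv = _finalize(C, labels, templates, polarity)
    return ClusterResult(templates=templates, labels=labels,
                         polarity=polarity, gev=gev_v, sigma2=sigma2,
                         cv=cv, q=q)


# ---------------------------------------------------------------------------
# Atomize-and-agglomerate hierarchical clustering
# ---------------------------------------------------------------------------

def aahc(
    maps,
    q_min: int,
    q_max: int,
    polarity: str = "ignore",
    gfp_normalize: bool = False,
) -> list[ClusterResult]:
    """Deterministic hierarchical microstate clustering.

    Starting from one cluster per map, the cluster with the lowest GEV
    contribution is repeatedly *atomized*: its members are freed and each
    is reassigned to the surviving cluster with the highest (squared, in
    polarity-ignore mode) spatial correlation. A :class:`ClusterResult`
    is recorded at every ``q`` in ``[q_min, q_max]``, ascending.

    Per-cluster GEV contributions are tracked through cached scatter
    matrices: in polarity-ignore mode the contribution of a cluster is
    exactly the largest eigenvalue of its members' outer-product sum,
    whose eigenvector is the template.
    """
    if polarity not in ("ignore", "respect"):
        raise ValueError("polarity must be 'ignore' or 'respect'")
    C = _prepare_maps(maps, gfp_normalize)
    T, N = C.shape
    if not (1 <= q_min <= q_max <= T):
        raise ValueError("need 1 <= q_min <= q_max <= T")
    norms2 = np.einsum("ij,ij->i", C, C)
    total = norms2.sum()

    # state per initial-slot cluster id
    alive = np.ones(T, dtype=bool)
    members: list[list[int]] = [[i] for i in range(T)]
    templates = _unit_rows(C.copy())
    scatter = np.einsum("ti,tj->tij", C, C)  # (T, N, N)
    sums = C.copy()  # member-vector sums, used in polarity-respect mode
    contrib = norms2.copy()

    results: dict[int, ClusterResult] = {}

    def record(k: int) -> ClusterResult:
        ids = np.flatnonzero(alive)
        remap = {int(c): j for j, c in enumerate(ids)}
        labels = np.empty(T, dtype=int)
        for c in ids:
            labels[members[c]] = remap[int(c)]
        tq = np.array([_fix_sign(templates[c]) for c in ids])
        g, sigma2, cv = _finalize(C, labels, tq, polarity)
        return ClusterResult(templates=tq, labels=labels, polarity=polarity,
                             gev=g, sigma2=sigma2, cv=cv, q=k)

    k = T
    if k <= q_max:
        results[k] = record(k)
    while k > q_min:
        ids = np.flatnonzero(alive)
        worst = int(ids[np.argmin(contrib[ids])])
        freed = members[worst]
        alive[worst] = False
        members[worst] = []
        k -= 1
        ids = np.flatnonzero(alive)
        P = C[freed] @ templates[ids].T  # (m, k)
        score = P**2 if polarity == "ignore" else P
        choice = ids[np.argmax(score, axis=1)]
        touched = set()
        for t_idx, r in zip(freed, choice):
            r = int(r)
            members[r].append(int(t_idx))
            scatter[r] += np.outer(C[t_idx], C[t_idx])
            sums[r] += C[t_idx]
            touched.add(r)
        for r in touched:
            if polarity == "ignore":
                templates[r], contrib[r] = _template_eig(scatter[r])
            else:
                templates[r] = _template_mean(
                    sums[r][None] / max(len(members[r]), 1)
                )
                contrib[r] = float(templates[r] @ scatter[r] @ templates[r])
        if q_min <= k <= q_max:
            results[k] = record(k)
    return [results[q] for q in sorted(results)]


# ---------------------------------------------------------------------------
# Fit quality and model selection
# ---------------------------------------------------------------------------

def gev(maps, labels, templates, polarity: str = "ignore") -> float:
    """Global explained variance of a labeling.

    GFP-weighted squared spatial correlation between each map and its
    assigned template, normalized by total GFP²; frames labeled
    :data:`UNASSIGNED` contribute nothing to the numerator.
    """
    C = _prepare_maps(maps)
    labels = np.asarray(labels, dtype=int)
    tmpl = _unit_rows(
        np.asarray(templates, float)
        - np.asarray(templates, float).mean(axis=1, keepdims=True)
    )
    norms2 = np.einsum("ij,ij->i", C, C)
    total = norms2.sum()
    if total == 0:
        return 0.0
    ok = labels >= 0
    proj = np.einsum("ij,ij->i", C[ok], tmpl[labels[ok]])
    return float((proj**2).sum() / total)


def cross_validation(result: ClusterResult,
                     n_electrodes: int | None = None) -> float:
    """Cross-validation score: residual variance × a degrees-of-freedom
    penalty that grows with the number of templates.

    ``cv = σ̂² · ((N − 1) / (N − 1 − q))²`` — lower is better; the penalty
    counteracts the automatic GEV gain of adding clusters. Requires
    ``N > q + 1``.
    """
    N = n_electrodes if n_electrodes is not None else result.templates.shape[1]
    q = result.q
    if N <= q + 1:
        raise ValueError(f"need N > q + 1 (N={N}, q={q})")
    return float(result.sigma2 * ((N - 1) / (N - 1 - q)) ** 2)


def dispersion(maps, result: ClusterResult) -> float:
    """Within-cluster dispersion W(q): summed squared distances of
    unit-normalized maps to their assigned template (sign-matched in
    polarity-ignore mode)."""
    C = _prepare_maps(maps)
    U = _unit_rows(C)
    labels = result.labels
    ok = labels >= 0
    r = np.einsum("ij,ij->i", U[ok], result.templates[labels[ok]])
    if result.polarity == "ignore":
        r = np.abs(r)
    return float(np.sum(2.0 - 2.0 * r))


def dispersion_curve(maps, results: list[ClusterResult]) -> DispersionCurve:
    """Assemble the per-q dispersion/CV/GEV table for model selection."""
    results = sorted(results, key=lambda r: r.q)
    qs = np.array([r.q for r in results])
    w = np.array([dispersion(maps, r) for r in results])
    N = results[0].templates.shape[1]
    cv = np.array([
        cross_validation(r) if N > r.q + 1 else np.nan for r in results
    ])
    g = np.array([r.gev for r in results])
    return DispersionCurve(qs=qs, w=w, n_electrodes=N, cv=cv, gev=g)


def kl_criterion(curve: DispersionCurve) -> int:
    """Krzanowski–Lai choice of the number of clusters.

    ``DIFF(q) = (q−1)^{2/N} W(q−1) − q^{2/N} W(q)`` and
    ``KL(q) = |DIFF(q)| / |DIFF(q+1)|``; the L-corner is the interior
    ``q`` maximizing KL (smallest ``q`` on ties). A flat KL profile —
    no value at least twice the median, as for featureless noise — is
    reported with a warning.
    """
    qs, w = curve.qs, curve.w
    if len(qs) < 3:
        raise ValueError("need dispersion at >= 3 consecutive q values")
    if np.any(np.diff(qs) != 1):
        raise ValueError("q values must be consecutive integers")
    p = curve.n_electrodes
    e = 2.0 / p
    diff = (qs[:-1].astype(float) ** e) * w[:-1] - (
        qs[1:].astype(float) ** e
    ) * w[1:]
    # diff[i] corresponds to DIFF(qs[i+1])
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.abs(diff[:-1]) / np.abs(diff[1:])
    kl = np.where(np.isfinite(kl), kl, 0.0)
    # kl[i] corresponds to interior q = qs[i+1]
    best = int(np.argmax(kl))
    if np.ptp(kl) == 0 or np.max(kl) < 2.0 * np.median(kl):
        warnings.warn(
            "KL profile has no sharp corner; the selected q is weakly "
            "supported", UserWarning, stacklevel=2,
        )
    return int(qs[best + 1])


# ---------------------------------------------------------------------------
# Temporal post-processing
# ---------------------------------------------------------------------------

def smooth_labels(
    labels,
    maps,
    templates,
    half_window_b: int = 3,
    penalty_lambda: float = 5.0,
    polarity: str = "ignore",
    max_iter: int = 100,
) -> np.ndarray:
    """Relabel frames balancing goodness of fit against temporal smoothness.

    Iteratively assigns each frame the template minimizing a residual
    fit term minus ``penalty_lambda`` times the count of identically
    labeled frames within ``±half_window_b``, until the labeling is a
    fixed point. ``penalty_lambda=0`` returns the labels unchanged;
    :data:`UNASSIGNED` frames are left untouched.
    """
    labels = np.asarray(labels, dtype=int).copy()
    if penalty_lambda == 0 or half_window_b == 0:
        return labels
    C = _prepare_maps(maps)
    T, N = C.shape
    tmpl = np.asarray(templates, dtype=float)
    q = tmpl.shape[0]
    norms2 = np.einsum("ij,ij->i", C, C)
    A = C @ tmpl.T
    A2 = A**2 if polarity == "ignore" else np.maximum(A, 0.0) ** 2
    resid = norms2[:, None] - A2  # (T, q)
    fixed = labels < 0
    for _ in range(max_iter):
        e = resid[np.arange(T), np.where(fixed, 0, labels)][~fixed].mean()
        e = max(e / (N - 1), 1e-300)
        counts = np.zeros((T, q))
        onehot = np.zeros((T, q))
        ok = ~fixed
        onehot[np.arange(T)[ok], labels[ok]] = 1.0
        csum = np.vstack([np.zeros((1, q)), np.cumsum(onehot, axis=0)])
        b = half_window_b
        lo = np.clip(np.arange(T) - b, 0, T)
        hi = np.clip(np.arange(T) + b + 1, 0, T)
        counts = csum[hi] - csum[lo] - onehot
        cost = resid / (2.0 * e * (N - 1)) - penalty_lambda * counts
        new = np.argmin(cost, axis=1)
        new[fixed] = labels[fixed]
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (start, stop_exclusive, label)."""
    out = []
    T = len(labels)
    start = 0
    for t in range(1, T + 1):
        if t == T or labels[t] != labels[start]:
            out.append((start, t, int(labels[start])))
            start = t
    return out


def reject_small_segments(
    labels,
    min_tf: int,
    maps=None,
    templates=None,
    polarity: str = "ignore",
) -> np.ndarray:
    """Absorb labeled runs shorter than ``min_tf`` into their neighbors.

    Each frame of a short run is relabeled to the better-correlated
    neighboring run's template when ``maps`` and ``templates`` are
    given, otherwise to the temporally nearer neighbor (ties go left).
    A short run with no labeled neighbor becomes :data:`UNASSIGNED`.
    """
    if min_tf < 1:
        raise ValueError("min_tf must be >= 1")
    labels = np.asarray(labels, dtype=int).copy()
    use_corr = maps is not None and templates is not None
    if use_corr:
        C = _prepare_maps(maps)
        tmpl = np.asarray(templates, dtype=float)
        A = C @ tmpl.T
        fit = np.abs(A) if polarity == "ignore" else A
    while True:
        runs = [r for r in _runs(labels) if r[2] != UNASSIGNED]
        short = [r for r in runs if r[1] - r[0] < min_tf]
        if not short:
            return labels
        short.sort(key=lambda r: (r[1] - r[0], r[0]))
        start, stop, _lab = short[0]
        left = labels[start - 1] if start > 0 else UNASSIGNED
        right = labels[stop] if stop < len(labels) else UNASSIGNED
        if left == UNASSIGNED and right == UNASSIGNED:
            labels[start:stop] = UNASSIGNED
            continue
        for t in range(start, stop):
            if left == UNASSIGNED:
                labels[t] = right
            elif right == UNASSIGNED:
                labels[t] = left
            elif use_corr:
                labels[t] = left if fit[t, left] >= fit[t, right] else right
            else:
                d_left = t - (start - 1)
                d_right = stop - t
                labels[t] = left if d_left <= d_right else right


def merge_clusters(
    result: ClusterResult,
    r_threshold: float,
    maps=None,
) -> ClusterResult:
    """Merge template pairs whose |spatial correlation| ≥ ``r_threshold``.

    The most-correlated pair is merged first and the template recomputed
    (from pooled member maps when ``maps`` is given, else from a
    frame-count-weighted combination of the two templates); repeats until
    no pair exceeds the threshold.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must be in (0, 1]")
    templates = result.templates.copy()
    labels = result.labels.copy()
    polarity = result.polarity
    C = _prepare_maps(maps) if maps is not None else None
    while templates.shape[0] > 1:
        q = templates.shape[0]
        R = templates @ templates.T
        corr = np.abs(R) if polarity == "ignore" else R
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < r_threshold:
            break
        i, j = (int(min(i, j)), int(max(i, j)))
        sign = np.sign(R[i, j]) or 1.0
        ni = int(np.sum(labels == i))
        nj = int(np.sum(labels == j))
        if C is not None:
            pooled_idx = (labels == i) | (labels == j)
            pooled = C[pooled_idx]
            if polarity == "ignore":
                merged, _ = _template_eig(pooled.T @ pooled)
            else:
                merged = _template_mean(pooled)
        else:
            merged = ni * templates[i] + sign * nj * templates[j]
            n = np.linalg.norm(merged)
            merged = templates[i] if n == 0 else merged / n
            merged = _fix_sign(merged)
        labels[labels == j] = i
        labels[labels > j] -= 1
        templates = np.delete(templates, j, axis=0)
        templates[i] = merged
    if C is not None:
        g, sigma2, cv = _finalize(C, labels, templates, polarity)
    else:
        g, sigma2, cv = result.gev, result.sigma2, float("nan")
    return ClusterResult(templates=templates, labels=labels,
                         polarity=polarity, gev=g, sigma2=sigma2, cv=cv,
                         q=templates.shape[0])


def sequentialize(result: ClusterResult, maps=None) -> ClusterResult:
    """Give temporally disjoint occurrences of one template distinct ids.

    Each maximal contiguous run of a template that occurs more than once
    becomes its own cluster; templates are recomputed per run from
    ``maps`` when given, otherwise duplicated. Segment boundaries are
    unchanged and labeled-frame totals conserved.
    """
    labels = result.labels
    runs = [r for r in _runs(labels) if r[2] != UNASSIGNED]
    occurrences: dict[int, list[tuple[int, int]]] = {}
    for start, stop, lab in runs:
        occurrences.setdefault(lab, []).append((start, stop))
    new_labels = np.full_like(labels, UNASSIGNED)
    new_templates: list[np.ndarray] = []
    C = _prepare_maps(maps) if maps is not None else None
    for start, stop, lab in runs:
        if len(occurrences[lab]) == 1:
            tmpl = result.templates[lab]
        elif C is not None:
            seg = C[start:stop]
            if result.polarity == "ignore":
                tmpl, _ = _template_eig(seg.T @ seg)
            else:
                tmpl = _template_mean(seg)
        else:
            tmpl = result.templates[lab]
        new_templates.append(tmpl)
        new_labels[start:stop] = len(new_templates) - 1
    tq = np.vstack(new_templates) if new_templates else result.templates[:0]
    if C is not None:
        g, sigma2, cv = _finalize(C, new_labels, tq, result.polarity)
    else:
        g, sigma2, cv = result.gev, result.sigma2, float("nan")
    return ClusterResult(templates=tq, labels=new_labels,
                         polarity=result.polarity, gev=g, sigma2=sigma2,
                         cv=cv, q=tq.shape[0])
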
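"""Pointwise, field-strength and topographic hypothesis tests.

Electrode-wise t-tests are reference-dependent and conflate strength and
topography; the global measures separate the two. :func:`gfp_test`
compares overall field strength per timeframe; :func:`tanova` is the
*topographic ANOVA* — a nonparametric randomization test on the global
map dissimilarity between the two conditions' group-mean maps. Because a
mean and a standard error of "topography" cannot be formed, the null
distribution is built by randomly exchanging each subject's condition
assignment (within-subject design, giving 2ⁿ possible assignments for n
subjects) or by shuffling group membership (between design), recomputing
the group means and their GMD each time. The p-value is the fraction of
permutation GMDs at least as large as the observed one, counting the
identity permutation, so p ≥ 1/n_used and the test is exact under
exchangeability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PointwiseTestResult",
    "TanovaResult",
    "pointwise_ttest",
    "gfp_test",
    "tanova",
    "fitstats_test",
]


@dataclass(frozen=True)
class PointwiseTestResult:
    """Per-electrode × timeframe t statistics, p-values and the
    significance mask surviving the chosen multiple-testing control."""

    t: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    correction: str
    alpha: float


@dataclass(frozen=True)
class TanovaResult:
    """Observed per-timeframe GMD between group means, permutation
    p-values, and the permutation bookkeeping."""

    observed_gmd: np.ndarray
    p_values: np.ndarray
    n_permutations_used: int
    design: str
    n: int
    exhaustive: bool


def _check_groups(condA, condB, paired: bool) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(condA, dtype=float)
    B = np.asarray(condB, dtype=float)
    if A.ndim != 3 or B.ndim != 3:
        raise ValueError("conditions must be subjects × channels × timeframes")
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("channel/timeframe dimensions must match")
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired design requires equal subject counts")
    if min(A.shape[0], B.shape[0]) < 2:
        raise ValueError("need at least 2 subjects per condition")
    return A, B


def _nan_to_null(t: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # zero-variance cells (e.g. identical conditions) are null, not NaN
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


def _duration_mask(raw: np.ndarray, min_duration_tf: int) -> np.ndarray:
    """Keep only runs of >= min_duration_tf consecutive True per row."""
    out = np.zeros_like(raw)
    for e in range(raw.shape[0]):
        row = raw[e]
        t = 0
        T = len(row)
        while t < T:
            if row[t]:
                start = t
                while t < T and row[t]:
                    t += 1
                if t - start >= min_duration_tf:
                    out[e, start:t] = True
            else:
                t += 1
    return out


def pointwise_ttest(
    condA,
    condB,
    paired: bool = True,
    alpha: float = 0.05,
    correction: str = "none",
    min_duration_tf: int = 1,
) -> PointwiseTestResult:
    """t-test of potentials at every electrode and timeframe.

    ``correction`` is ``"none"``, ``"bonferroni"`` (α divided by the
    N·T comparisons) or ``"duration"`` (uncorrected α, but only effects
    lasting at least ``min_duration_tf`` consecutive frames per
    electrode are retained). This analysis is reference-dependent —
    interpret alongside the global tests.
    """
    A, B = _check_groups(condA, condB, paired)
    if paired:
        res = sps.ttest_rel(A, B, axis=0)
    else:
        res = sps.ttest_ind(A, B, axis=0)
    t, p = _nan_to_null(res.statistic, res.pvalue)
    if correction == "none":
        mask = p < alpha
    elif correction == "bonferroni":
        mask = p < alpha / p.size
    elif correction == "duration":
        if min_duration_tf < 1:
            raise ValueError("min_duration_tf must be >= 1")
        mask = _duration_mask(p < alpha, min_duration_tf)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return PointwiseTestResult(t=t, p=p, sig_mask=mask,
                               correction=correction, alpha=alpha)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _within_assignments(
    n: int, n_perm: int, exhaustive_threshold: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """0/1 swap matrix (P, n); row of zeros = identity assignment."""
    if 2**n <= exhaustive_threshold:
        W = np.array(list(product((0, 1), repeat=n)), dtype=float)
        return W, True
    W = rng.integers(0, 2, size=(n_perm - 1, n)).astype(float)
    W = np.vstack([np.zeros((1, n)), W])
    return W, False


def _between_assignments(
    n1: int, n2: int, n_perm: int, exhaustive_threshold: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Boolean membership matrix (P, n1+n2); True = assigned to group A."""
    n = n1 + n2
    from math import comb

    if comb(n, n1) <= exhaustive_threshold:
        rows = []
        for combo in combinations(range(n), n1):
            row = np.zeros(n, dtype=bool)
            row[list(combo)] = True
            rows.append(row)
        M = np.array(rows)
        identity = np.zeros(n, dtype=bool)
        identity[:n1] = True
        # move the identity assignment to row 0
        k = int(np.flatnonzero((M == identity).all(axis=1))[0])
        M[[0, k]] = M[[k, 0]]
        return M, True
    rows = [np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])]
    for _ in range(n_perm - 1):
        perm = rng.permutation(n)
        row = np.zeros(n, dtype=bool)
        row[perm[:n1]] = True
        rows.append(row)
    return np.array(rows), False


def _gmd_frames(mA: np.ndarray, mB: np.ndarray) -> np.ndarray:
    """GMD per frame between map stacks of shape (..., N, T).

    Flat frames (zero GFP in either mean) yield NaN.
    """
    def normed(x):
        c = x - x.mean(axis=-2, keepdims=True)
        g = np.sqrt(np.mean(c**2, axis=-2, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = c / g
        out = np.where(g > 0, out, np.nan)
        return out

    d = normed(mA) - normed(mB)
    return np.sqrt(np.mean(d**2, axis=-2))


def gfp_test(
    condA,
    condB,
    paired: bool = True,
    method: str = "ttest",
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    exhaustive_threshold: int = 2**16,
) -> np.ndarray:
    """Per-timeframe test of global field power differences.

    The per-subject statistic is the GFP of each subject's map at each
    timeframe. ``method="ttest"`` runs paired/unpaired t-tests;
    ``method="permutation"`` permutes condition assignment within
    subjects (paired; exhaustive over all 2ⁿ assignments when feasible)
    or group membership (unpaired). Returns two-sided p per timeframe.
    """
    A, B = _check_groups(condA, condB, paired)
    gA = np.sqrt(np.mean(
        (A - A.mean(axis=1, keepdims=True)) ** 2, axis=1))  # (nA, T)
    gB = np.sqrt(np.mean(
        (B - B.mean(axis=1, keepdims=True)) ** 2, axis=1))
    if method == "ttest":
        if paired:
            res = sps.ttest_rel(gA, gB, axis=0)
        else:
            res = sps.ttest_ind(gA, gB, axis=0)
        _, p = _nan_to_null(res.statistic, res.pvalue)
        return p
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    if paired:
        D = gA - gB  # (n, T)
        n = D.shape[0]
        W, _ = _within_assignments(n, n_perm, exhaustive_threshold, rng)
        signs = 1.0 - 2.0 * W  # (P, n)
        stats_perm = np.abs(signs @ D) / n  # (P, T)
    else:
        pooled = np.vstack([gA, gB])
        M, _ = _between_assignments(gA.shape[0], gB.shape[0], n_perm,
                                    exhaustive_threshold, rng)
        n1, n2 = gA.shape[0], gB.shape[0]
        mA = (M.astype(float) @ pooled) / n1
        mB = ((~M).astype(float) @ pooled) / n2
        stats_perm = np.abs(mA - mB)
    observed = stats_perm[0]
    p = (stats_perm >= observed[None, :] - 1e-12).sum(axis=0) / len(stats_perm)
    return p


def tanova(
    condA_maps,
    condB_maps,
    design: str = "within",
    n_perm: int = 5000,
    seed: int | None = None,
    exhaustive_threshold: int = 2**16,
    chunk: int = 256,
    normalize_subjects: bool = False,
) -> TanovaResult:
    """Topographic ANOVA: randomization test on group-mean map GMD.

    Per timeframe the observed statistic is the GMD between the two
    conditions' GFP-normalized group-mean maps. The null exchanges each
    subject's condition assignment (``design="within"``) or shuffles
    group membership (``"between"``), recomputes group means and their
    GMD. Enumeration is exhaustive when the permutation space does not
    exceed ``exhaustive_threshold``; otherwise ``n_perm`` Monte-Carlo
    draws (the identity assignment always included) with ``seed``.
    Frames where a group mean is flat get NaN p-values.

    Group means are GFP-normalized inside the GMD (always);
    ``normalize_subjects`` additionally scales every subject map to unit
    GFP before averaging, removing individual strength differences from
    the statistic entirely.
    """
    if design not in ("within", "between"):
        raise ValueError("design must be 'within' or 'between'")
    A = np.asarray(condA_maps, dtype=float)
    B = np.asarray(condB_maps, dtype=float)
    A, B = _check_groups(A, B, paired=(design == "within"))
    if normalize_subjects:
        def unit_gfp(X):
            c = X - X.mean(axis=1, keepdims=True)
            g = np.sqrt(np.mean(c**2, axis=1, keepdims=True))
            if np.any(g <= 0):
                raise ValueError("flat subject map: cannot normalize")
            return c / g

        A, B = unit_gfp(A), unit_gfp(B)
    rng = np.random.default_rng(seed)
    T = A.shape[2]
    if design == "within":
        n = A.shape[0]
        W, exhaustive = _within_assignments(n, n_perm, exhaustive_threshold,
                                            rng)
        P = W.shape[0]
        Abar = A.mean(axis=0)  # (N, T)
        Bbar = B.mean(axis=0)
        D = (B - A).reshape(n, -1)  # swaps move D/n between the means
        count = np.zeros(T)
        observed = _gmd_frames(Abar, Bbar)
        for s in range(0, P, chunk):
            Wc = W[s : s + chunk]
            shift = (Wc @ D).reshape(len(Wc), *A.shape[1:]) / n
            mA = Abar[None] + shift
            mB = Bbar[None] - shift
            g = _gmd_frames(mA, mB)  # (chunk, T)
            count += np.nansum(g >= observed[None, :] - 1e-12, axis=0)
        n_used = P
    else:
        n1, n2 = A.shape[0], B.shape[0]
        pooled = np.vstack([A, B]).reshape(n1 + n2, -1)
        M, exhaustive = _between_assignments(n1, n2, n_perm,
                                             exhaustive_threshold, rng)
        P = M.shape[0]
        observed = _gmd_frames(A.mean(axis=0), B.mean(axis=0))
        count = np.zeros(T)
        for s in range(0, P, chunk):
            Mc = M[s : s + chunk]
            mA = (Mc.astype(float) @ pooled).reshape(
                len(Mc), *A.shape[1:]) / n1
            mB = ((~Mc).astype(float) @ pooled).reshape(
                len(Mc), *A.shape[1:]) / n2
            g = _gmd_frames(mA, mB)
            count += np.nansum(g >= observed[None, :] - 1e-12, axis=0)
        n_used = P
    n_subj = A.shape[0] if design == "within" else A.shape[0] + B.shape[0]
    p = np.where(np.isfinite(observed), count / n_used, np.nan)
    return TanovaResult(observed_gmd=observed, p_values=p,
                        n_permutations_used=n_used, design=design,
                        n=n_subj, exhaustive=exhaustive)


def fitstats_test(
    fit_csv,
    parameter: str,
    paired: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """t-tests per template on one back-fitting parameter.

    ``fit_csv`` is a path or DataFrame in the tidy layout written by
    :func:`eegtopo.backfitting.export_fit_csv`; exactly two conditions
    are compared. Returns one row per template with t, p and the
    significance flag at ``alpha``.
    """
    df = fit_csv if isinstance(fit_csv, pd.DataFrame) else pd.read_csv(
        Path(fit_csv))
    for col in ("subject", "condition", "template", parameter):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in fit statistics")
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    rows = []
    for tmpl, sub in df.groupby("template"):
        wide = sub.pivot(index="subject", columns="condition",
                         values=parameter)
        a, b = wide[conds[0]].to_numpy(), wide[conds[1]].to_numpy()
        if paired:
            res = sps.ttest_rel(a, b)
        else:
            res = sps.ttest_ind(a[~np.isnan(a)], b[~np.isnan(b)])
        t, p = _nan_to_null(np.asarray(res.statistic),
                            np.asarray(res.pvalue))
        rows.append(dict(template=tmpl, t=float(t), p=float(p),
                         significant=bool(p < alpha)))
    return pd.DataFrame(rows)
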
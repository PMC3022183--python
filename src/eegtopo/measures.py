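"""Reference-free global topographic measures.

Two scalars summarize a scalp potential map ``u`` of ``N`` electrodes:

* **Global Field Power** — the spatial standard deviation of the
  average-referenced map,

  .. math:: \\mathrm{GFP}(u) = \\sqrt{\\tfrac{1}{N}\\sum_i (u_i - \\bar u)^2}

  a one-number index of overall field strength at one instant. It is
  invariant under any rereferencing, which only adds a constant per map.

* **Global Map Dissimilarity** — the root-mean-square difference between
  two average-referenced, GFP-normalized maps,

  .. math::
     \\mathrm{GMD}(u, v) = \\sqrt{\\tfrac{1}{N}\\sum_i
        \\left(\\tfrac{u_i-\\bar u}{\\mathrm{GFP}(u)}
        - \\tfrac{v_i-\\bar v}{\\mathrm{GFP}(v)}\\right)^2}

  which is 0 for identical topographies and reaches 2 for the same
  topography with reversed polarity. GMD relates to the spatial Pearson
  correlation ``r`` across electrodes by ``GMD² = 2(1 − r)``.

Both functions average-reference their inputs internally, so the caller's
choice of recording reference is irrelevant — the reference-independence
of topographic analysis is structural, not a calling convention.
"""

from __future__ import annotations

import numpy as np

from .io import Recording

__all__ = [
    "gfp",
    "gmd",
    "spatial_correlation",
    "gfp_curve",
    "gmd_curve",
    "gfp_normalize",
    "avg_ref",
]


def _as_map(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("a topographic map must be a vector of >= 2 values")
    if not np.all(np.isfinite(u)):
        raise ValueError("map contains non-finite values")
    return u


def avg_ref(u: np.ndarray, axis: int = -1) -> np.ndarray:
    """Subtract the mean over electrodes (average reference)."""
    u = np.asarray(u, dtype=float)
    return u - u.mean(axis=axis, keepdims=True)


def gfp(u) -> float:
    """Global Field Power of one map: spatial SD over electrodes.

    Uses the population formula (divide by ``N``). The input reference is
    irrelevant because the electrode mean is subtracted first.
    """
    u = _as_map(u)
    centered = u - u.mean()
    return float(np.sqrt(np.mean(centered**2)))


def _normalized(u: np.ndarray) -> np.ndarray:
    """Average-reference and divide by GFP; error on flat maps."""
    centered = u - u.mean()
    g = np.sqrt(np.mean(centered**2))
    if g <= 0.0:
        raise ValueError("zero-GFP (flat) map: GFP normalization undefined")
    return centered / g


def gmd(u, v) -> float:
    """Global Map Dissimilarity between two maps, in ``[0, 2]``.

    Raises
    ------
    ValueError
        If map lengths differ or either map is flat (zero GFP).
    """
    u, v = _as_map(u), _as_map(v)
    if u.shape != v.shape:
        raise ValueError("maps must have equal electrode counts")
    diff = _normalized(u) - _normalized(v)
    return float(np.sqrt(np.mean(diff**2)))


def spatial_correlation(u, v) -> float:
    """Pearson correlation across electrodes of two average-referenced maps.

    Satisfies ``GMD² = 2(1 − r)`` exactly (up to rounding).
    """
    u, v = _as_map(u), _as_map(v)
    if u.shape != v.shape:
        raise ValueError("maps must have equal electrode counts")
    un, vn = _normalized(u), _normalized(v)
    return float(np.mean(un * vn))


def gfp_curve(rec: Recording | np.ndarray) -> np.ndarray:
    """GFP at every timeframe: vector of length ``T`` (µV)."""
    data = rec.data if isinstance(rec, Recording) else np.asarray(rec, float)
    centered = data - data.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=0))


def gmd_curve(rec: Recording | np.ndarray) -> np.ndarray:
    """GMD between successive timeframes: vector of length ``T − 1``.

    Timeframe pairs involving a flat (zero-GFP) map yield NaN — flagged
    missing rather than silently propagated.
    """
    data = rec.data if isinstance(rec, Recording) else np.asarray(rec, float)
    centered = data - data.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(centered**2, axis=0))
    out = np.full(data.shape[1] - 1, np.nan)
    ok = g > 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(ok, 1.0, np.nan) * centered / np.where(ok, g, 1.0)
    diff = normed[:, 1:] - normed[:, :-1]
    valid = ok[1:] & ok[:-1]
    out[valid] = np.sqrt(np.mean(diff[:, valid] ** 2, axis=0))
    return out


def gfp_normalize(rec: Recording, mode: str = "mean_gfp") -> Recording:
    """Scale a recording by its GFP.

    ``"per_timeframe"`` divides every map by its own GFP so each frame has
    GFP 1 (used before clustering when topography alone should matter);
    ``"mean_gfp"`` divides the whole recording by the temporal mean GFP
    (used to equate overall field strength across subjects).
    """
    curve = gfp_curve(rec)
    if mode == "per_timeframe":
        if np.any(curve <= 0.0):
            raise ValueError("zero-GFP timeframe: per-timeframe scaling undefined")
        return rec.with_data(rec.data / curve[None, :])
    if mode == "mean_gfp":
        m = curve.mean()
        if m <= 0.0:
            raise ValueError("mean GFP is zero")
        return rec.with_data(rec.data / m)
    raise ValueError(f"unknown mode {mode!r}")
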
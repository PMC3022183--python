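"""Synthetic montages, template topographies and microstate/ERP data.

Every analysis in this package is exercisable without any recorded EEG:
this module generates electrode montages on the upper hemisphere,
dipolar-looking template maps with bounded mutual correlation, piecewise
stable "microstate" EEG (abrupt template switches with geometric run
lengths, an oscillatory GFP envelope and white sensor noise at a
controlled SNR), and two-condition ERP group datasets with planted
topographic or field-strength effects — each with its ground truth, and
fully deterministic per seed (NumPy PCG64 via ``default_rng``).

The generator emulates the statistical structure the topographic methods
assume — stable topographies, abrupt switches, additive sensor noise —
not the biophysics of real EEG (no volume conduction, no 1/f spectrum,
no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ElectrodeMontage, Recording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_montage",
    "make_templates",
    "simulate_microstate_eeg",
    "simulate_erp_group",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic data regimes.

    ``snr`` is the ratio of mean signal GFP to mean noise GFP;
    ``mean_duration_tf`` the mean microstate run length in timeframes;
    ``effect_type`` plants either a topography rotation (equal field
    strength) or a GFP scaling (equal topography) into condition B of
    an ERP group dataset, inside ``effect_window`` (defaults to the
    middle third of the epoch).
    """

    n_electrodes: int = 19
    n_templates: int = 4
    mean_duration_tf: int = 20
    duration_jitter: float = 0.0
    sampling_rate_hz: float = 250.0
    snr: float = 5.0
    n_timeframes: int = 5000
    seed: int = 0
    oscillatory: bool = False
    n_subjects: int = 12
    effect_type: str = "none"
    effect_size: float = 0.5
    effect_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        for name in ("n_electrodes", "n_templates", "mean_duration_tf",
                     "n_timeframes", "n_subjects"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_type not in ("none", "topographic", "gfp"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually embedded: true templates, the true
    per-frame state sequence, and per-subject noise seeds."""

    templates: np.ndarray
    labels: np.ndarray
    noise_seeds: tuple[int, ...] = ()
    effect_window: tuple[int, int] | None = None
    effect_template: np.ndarray | None = None


def make_montage(n: int, seed: int | None = None) -> ElectrodeMontage:
    """~Uniform electrode positions on the upper unit hemisphere.

    Golden-angle spiral with a small seeded angular jitter; labels are
    ``E1..En``.
    """
    if n < 4:
        raise ValueError("need at least 4 electrodes")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    z = (i + 0.5) / n  # heights in (0, 1): upper hemisphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = i * golden + rng.uniform(-0.05, 0.05, size=n)
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    names = tuple(f"E{k + 1}" for k in range(n))
    return ElectrodeMontage(names=names, positions=pos)


def _avg_ref_unit_gfp(u: np.ndarray) -> np.ndarray:
    c = u - u.mean()
    g = np.sqrt(np.mean(c**2))
    if g == 0:
        raise ValueError("degenerate flat template")
    return c / g


def make_templates(
    montage: ElectrodeMontage,
    k: int,
    seed: int | None = None,
    max_abs_corr: float = 0.7,
    max_draws: int = 1000,
) -> np.ndarray:
    """``k`` dipolar-looking maps with pairwise |r| ≤ ``max_abs_corr``.

    Each template is the inner product of electrode positions with a
    random axis plus a quadratic curvature term along a second random
    axis, average-referenced and scaled to unit GFP. Templates too
    correlated with those already accepted are rejection-sampled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    P = montage.positions
    out: list[np.ndarray] = []
    draws = 0
    while len(out) < k:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not draw {k} templates with pairwise |r| <= "
                f"{max_abs_corr}; try fewer templates"
            )
        draws += 1
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b = rng.normal(size=3)
        b /= np.linalg.norm(b)
        curvature = rng.uniform(0.2, 0.8)
        u = P @ a + curvature * (P @ b) ** 2
        u = _avg_ref_unit_gfp(u)
        n = len(u)
        if all(abs(float(u @ v) / n) <= max_abs_corr for v in out):
            out.append(u)
    return np.array(out)


def _state_sequence(cfg: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Successive template indices, geometric run lengths, no repeats."""
    labels = np.empty(cfg.n_timeframes, dtype=int)
    t = 0
    state = int(rng.integers(cfg.n_templates))
    p = 1.0 / cfg.mean_duration_tf
    while t < cfg.n_timeframes:
        length = int(rng.geometric(p))
        if cfg.duration_jitter > 0:
            length = int(round(length + rng.normal(0, cfg.duration_jitter)))
        length = max(1, length)
        labels[t : t + length] = state
        t += length
        if cfg.n_templates > 1:
            step = int(rng.integers(1, cfg.n_templates))
            state = (state + step) % cfg.n_templates
    return labels


def simulate_microstate_eeg(
    cfg: SimulationConfig,
    montage: ElectrodeMontage | None = None,
    templates: np.ndarray | None = None,
) -> tuple[Recording, GroundTruth]:
    """Piecewise-stable EEG: template runs × GFP envelope + white noise.

    The per-frame map is the active template scaled by a rectified
    ~10 Hz sinusoid (floored at 0.1 so no frame is flat); with
    ``cfg.oscillatory`` the envelope keeps its sign, flipping map
    polarity every half cycle (for polarity-ignore tests). Spatially
    white Gaussian sensor noise is scaled so mean signal GFP over mean
    noise GFP equals ``cfg.snr``.
    """
    rng = np.random.default_rng(cfg.seed)
    if montage is None:
        montage = make_montage(cfg.n_electrodes, seed=int(
            rng.integers(2**31)))
    if templates is None:
        templates = make_templates(montage, cfg.n_templates,
                                   seed=int(rng.integers(2**31)))
    N = len(montage)
    T = cfg.n_timeframes
    labels = _state_sequence(cfg, rng)
    tt = np.arange(T) / cfg.sampling_rate_hz
    osc = np.sin(2 * np.pi * 10.0 * tt + rng.uniform(0, 2 * np.pi))
    mag = np.maximum(np.abs(osc), 0.1)
    env = np.where(osc >= 0, mag, -mag) if cfg.oscillatory else mag
    signal = templates[labels].T * env[None, :]  # (N, T)
    sig_gfp = np.sqrt(np.mean(
        (signal - signal.mean(axis=0)) ** 2, axis=0)).mean()
    noise = rng.normal(size=(N, T))
    noise_gfp = np.sqrt(np.mean(
        (noise - noise.mean(axis=0)) ** 2, axis=0)).mean()
    noise *= sig_gfp / (cfg.snr * noise_gfp)
    rec = Recording(data=signal + noise,
                    sampling_rate=cfg.sampling_rate_hz,
                    montage=montage, reference="average")
    return rec, GroundTruth(templates=templates, labels=labels)


def _erp_envelope(cfg: SimulationConfig, T: int) -> np.ndarray:
    """Smooth positive component envelope: raised-cosine bumps."""
    t = np.arange(T, dtype=float)
    period = max(cfg.mean_duration_tf * 2, 4)
    return 0.15 + np.sin(np.pi * (t % period) / period) ** 2


def simulate_erp_group(
    cfg: SimulationConfig,
    montage: ElectrodeMontage | None = None,
    templates: np.ndarray | None = None,
) -> tuple[list[Recording], list[Recording], GroundTruth]:
    """Two-condition ERP group data with a known planted effect.

    A deterministic template sequence (consecutive blocks of
    ``mean_duration_tf`` frames) scaled by a smooth envelope forms the
    noise-free ERP; each subject observes it plus independent white
    noise at ``cfg.snr``. Inside ``effect_window`` condition B either
    uses a rotated template with spatial correlation ``1 − effect_size``
    to A's at equal GFP (``"topographic"``), scales amplitude by
    ``1 + effect_size`` (``"gfp"``), or is identical (``"none"``).
    """
    rng = np.random.default_rng(cfg.seed)
    if montage is None:
        montage = make_montage(cfg.n_electrodes, seed=int(
            rng.integers(2**31)))
    if templates is None:
        templates = make_templates(montage, cfg.n_templates,
                                   seed=int(rng.integers(2**31)))
    N = len(montage)
    T = cfg.n_timeframes
    block = cfg.mean_duration_tf
    labels = (np.arange(T) // block) % cfg.n_templates
    env = _erp_envelope(cfg, T)
    base = templates[labels].T * env[None, :]  # (N, T)
    window = cfg.effect_window or (T // 3, 2 * T // 3 - 1)
    w0, w1 = window
    sigA = base
    sigB = base.copy()
    effect_template = None
    if cfg.effect_type == "topographic":
        r_target = 1.0 - cfg.effect_size
        rot = []
        for k in range(cfg.n_templates):
            tau = templates[k]
            rnd = _avg_ref_unit_gfp(rng.normal(size=N))
            n = N
            perp = rnd - (float(rnd @ tau) / n) * tau
            perp = _avg_ref_unit_gfp(perp)
            rot.append(r_target * tau + np.sqrt(1 - r_target**2) * perp)
        rot = np.array(rot)  # unit GFP, corr r_target with originals
        effect_template = rot
        sigB[:, w0 : w1 + 1] = rot[labels[w0 : w1 + 1]].T * env[w0 : w1 + 1]
    elif cfg.effect_type == "gfp":
        sigB[:, w0 : w1 + 1] *= 1.0 + cfg.effect_size
    sig_gfp = np.sqrt(np.mean(
        (base - base.mean(axis=0)) ** 2, axis=0)).mean()
    noise_scale = sig_gfp / cfg.snr
    condA, condB = [], []
    noise_seeds = []
    for _s in range(cfg.n_subjects):
        sA = int(rng.integers(2**31))
        sB = int(rng.integers(2**31))
        noise_seeds.extend([sA, sB])
        nA = np.random.default_rng(sA).normal(size=(N, T))
        nB = np.random.default_rng(sB).normal(size=(N, T))
        for nz in (nA, nB):
            g = np.sqrt(np.mean((nz - nz.mean(axis=0)) ** 2, axis=0)).mean()
            nz *= noise_scale / g
        condA.append(Recording(data=sigA + nA,
                               sampling_rate=cfg.sampling_rate_hz,
                               montage=montage, reference="average"))
        condB.append(Recording(data=sigB + nB,
                               sampling_rate=cfg.sampling_rate_hz,
                               montage=montage, reference="average"))
    gt = GroundTruth(templates=templates, labels=labels,
                     noise_seeds=tuple(noise_seeds), effect_window=window,
                     effect_template=effect_template)
    return condA, condB, gt
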
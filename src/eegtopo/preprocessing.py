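"""Standard per-channel conditioning upstream of topographic analysis.

Rereferencing, Butterworth filtering (band-pass / notch / DC removal),
envelope extraction, anti-aliased downsampling, epoching around markers
with amplitude-window artifact rejection, and epoch averaging with
baseline correction. All temporal operations act per channel and never
mix channels; rereferencing is the only cross-channel step, and it leaves
the GFP timecourse untouched because it only adds a constant per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import MarkerList, Recording

__all__ = [
    "EpochSet",
    "rereference",
    "filter_recording",
    "envelope",
    "downsample",
    "extract_epochs",
    "reject_epochs_amplitude",
    "average_epochs",
]


@dataclass(frozen=True)
class EpochSet:
    """Epochs cut around markers: ``n_epochs × N × L`` (µV).

    ``kept_mask`` flags epochs surviving artifact rejection; ``n_dropped``
    counts marker windows that fell outside the recording and were never
    materialized.
    """

    epochs: np.ndarray
    sampling_rate: float
    event_label: str
    kept_mask: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        if ep.ndim != 3:
            raise ValueError("epochs must be n_epochs × channels × samples")
        mask = np.asarray(self.kept_mask, dtype=bool)
        if mask.shape != (ep.shape[0],):
            raise ValueError("kept_mask length must equal n_epochs")
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "kept_mask", mask)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


def rereference(rec: Recording, target: str | list[str]) -> Recording:
    """Recompute potentials against a new reference.

    ``target`` may be ``"average"``, a single channel name, or a list of
    channel names whose mean becomes the reference. Any rereference adds a
    constant per timeframe, so GFP (and every topographic measure) is
    unchanged.
    """
    data = rec.data
    names = list(rec.channel_names)
    if target == "average":
        ref = data.mean(axis=0, keepdims=True)
        tag = "average"
    else:
        targets = [target] if isinstance(target, str) else list(target)
        idx = []
        for name in targets:
            if name not in names:
                raise ValueError(f"unknown reference channel {name!r}")
            idx.append(names.index(name))
        ref = data[idx].mean(axis=0, keepdims=True)
        tag = "channel:" + "+".join(targets)
    return rec.with_data(data - ref, reference=tag)


def _sos_filter(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def filter_recording(
    rec: Recording,
    low_hz: float | None = None,
    high_hz: float | None = None,
    notch_hz: float | None = None,
    order: int = 2,
    remove_dc: bool = False,
    zero_phase: bool = True,
    notch_q: float = 30.0,
) -> Recording:
    """Butterworth band-pass / high-pass / low-pass, notch, and DC removal.

    ``low_hz``/``high_hz`` are the band edges (either may be omitted);
    ``order`` is the Butterworth order of the single-pass design (an
    order-2 low-pass rolls off at −12 dB/octave). Filtering is zero-phase
    (forward-backward) by default so later segment boundaries are not
    phase-shifted; set ``zero_phase=False`` for the causal single pass.
    The notch is a narrow band-stop of quality factor ``notch_q``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = rec.sampling_rate / 2.0
    for c in (low_hz, high_hz, notch_hz):
        if c is not None and not (0.0 < c < nyq):
            raise ValueError(f"cutoff {c} Hz outside (0, Nyquist={nyq})")
    data = rec.data
    if remove_dc:
        data = data - data.mean(axis=1, keepdims=True)
    if low_hz is not None and high_hz is not None:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=rec.sampling_rate, output="sos")
        data = _sos_filter(data, sos, zero_phase)
    elif low_hz is not None:
        sos = signal.butter(order, low_hz, btype="highpass",
                            fs=rec.sampling_rate, output="sos")
        data = _sos_filter(data, sos, zero_phase)
    elif high_hz is not None:
        sos = signal.butter(order, high_hz, btype="lowpass",
                            fs=rec.sampling_rate, output="sos")
        data = _sos_filter(data, sos, zero_phase)
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.sampling_rate)
        if zero_phase:
            data = signal.filtfilt(b, a, data, axis=-1)
        else:
            data = signal.lfilter(b, a, data, axis=-1)
    return rec.with_data(data)


def envelope(rec: Recording, mode: str = "abs",
             smooth_hz: float = 10.0) -> Recording:
    """Rectify (absolute or squared values) then low-pass smooth."""
    if mode == "abs":
        rect = np.abs(rec.data)
    elif mode == "square":
        rect = rec.data**2
    else:
        raise ValueError(f"unknown envelope mode {mode!r}")
    smoothed = filter_recording(
        rec.with_data(rect), high_hz=smooth_hz, order=2
    )
    return smoothed


def downsample(rec: Recording, factor: int) -> Recording:
    """Decimate by an integer factor after anti-alias low-pass filtering.

    A zero-phase Butterworth low-pass at 80% of the new Nyquist suppresses
    frequencies that would alias; the sampling rate is divided by
    ``factor`` and ``T`` becomes ``floor(T / factor)``.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError("downsampling factor must be an integer >= 2")
    factor = int(factor)
    new_rate = rec.sampling_rate / factor
    sos = signal.butter(8, 0.8 * new_rate / 2.0, btype="lowpass",
                        fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    t_new = rec.n_timeframes // factor
    decimated = filtered[:, : t_new * factor : factor]
    return rec.with_data(decimated, sampling_rate=new_rate, markers=None)


def extract_epochs(
    rec: Recording,
    markers: MarkerList,
    label: str,
    pre_tf: int,
    post_tf: int,
) -> EpochSet:
    """Cut epochs ``[onset − pre_tf, onset + post_tf]`` (inclusive).

    Windows extending outside the recording are dropped and counted in
    ``n_dropped``; an absent label yields an empty EpochSet.
    """
    if pre_tf < 0 or post_tf < 0:
        raise ValueError("pre_tf and post_tf must be >= 0")
    length = pre_tf + post_tf + 1
    chunks, dropped = [], 0
    for onset, _offset, lab in markers.entries:
        if lab != label:
            continue
        start = onset - pre_tf
        stop = onset + post_tf + 1
        if start < 0 or stop > rec.n_timeframes:
            dropped += 1
            continue
        chunks.append(rec.data[:, start:stop])
    if chunks:
        epochs = np.stack(chunks)
    else:
        epochs = np.empty((0, rec.n_channels, length))
    return EpochSet(
        epochs=epochs,
        sampling_rate=rec.sampling_rate,
        event_label=label,
        kept_mask=np.ones(len(chunks), dtype=bool),
        n_dropped=dropped,
    )


def reject_epochs_amplitude(es: EpochSet, max_abs_uv: float) -> EpochSet:
    """Flag epochs whose any sample exceeds ``±max_abs_uv`` µV.

    Only the kept-mask changes; epoch data is untouched.
    """
    if max_abs_uv <= 0:
        raise ValueError("max_abs_uv must be > 0")
    if es.n_epochs == 0:
        return es
    within = np.all(np.abs(es.epochs) <= max_abs_uv, axis=(1, 2))
    return replace(es, kept_mask=es.kept_mask & within)


def average_epochs(
    es: EpochSet, baseline_tf: tuple[int, int] | None = None
) -> Recording:
    """Average kept epochs into an ERP, optionally baseline-correcting.

    ``baseline_tf`` is an inclusive ``(start, end)`` window in epoch-local
    timeframes; each epoch's per-channel mean over that window is
    subtracted before averaging.
    """
    kept = es.epochs[es.kept_mask]
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs to average")
    if baseline_tf is not None:
        b0, b1 = baseline_tf
        if not (0 <= b0 <= b1 < kept.shape[2]):
            raise ValueError("baseline window outside epoch")
        kept = kept - kept[:, :, b0 : b1 + 1].mean(axis=2, keepdims=True)
    erp = kept.mean(axis=0)
    return Recording(data=erp, sampling_rate=es.sampling_rate,
                     reference="unknown")
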
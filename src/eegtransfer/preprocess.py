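"""Resting-state EEG preprocessing chain.

The chain prepares a raw 3-channel recording for image encoding:

1. per-channel min–max normalization to [0, 1];
2. core-segment selection — keep the 30%–70% central fraction, since the
   start and end of a resting recording are contaminated by settling-in
   and wrap-up effects;
3. a three-stage zero-phase Butterworth cascade: 1 Hz high-pass, [48, 52] Hz
   band-stop (mains notch), [0.5, 35] Hz band-pass;
4. segmentation into contiguous non-overlapping 1-second (250-sample)
   windows.

Conventions used throughout: 0-based sample indices, half-open windows
``[start, start+L)``, ``floor`` for fractional positions.

By default the whole core segment is filtered once and then windowed
(filtering 1-s snippets individually would create severe edge transients);
the filter-each-window order is available for fidelity experiments via
``filter_per_window=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .cohort import Recording
from .errors import DegenerateInputError, InvalidArgumentError

DEFAULT_WINDOW_LEN = 250
DEFAULT_CORE_FRACTION = (0.30, 0.70)


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of the three-stage filter cascade.

    Defaults: 4th-order Butterworth high-pass at 1 Hz and band-pass over
    [0.5, 35] Hz, 2nd-order Butterworth band-stop over [48, 52] Hz, each
    applied forward–backward (zero phase) so waveform alignment in the
    rendered images is preserved.
    """

    highpass_cutoff_hz: float = 1.0
    notch_band_hz: tuple[float, float] = (48.0, 52.0)
    bandpass_band_hz: tuple[float, float] = (0.5, 35.0)
    highpass_order: int = 4
    notch_order: int = 2
    bandpass_order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.highpass_cutoff_hz <= 0:
            raise InvalidArgumentError("highpass cutoff must be positive")
        for name in ("notch_band_hz", "bandpass_band_hz"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise InvalidArgumentError(f"{name} must be a nonempty positive band")
        for name in ("highpass_order", "notch_order", "bandpass_order"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be ≥ 1")

    def validate_for_fs(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.highpass_cutoff_hz >= nyq:
            raise InvalidArgumentError("highpass cutoff at or above Nyquist")
        if self.notch_band_hz[1] >= nyq or self.bandpass_band_hz[1] >= nyq:
            raise InvalidArgumentError("filter band extends to or above Nyquist")

    def sos_stages(self, fs: float) -> list[np.ndarray]:
        """Second-order-section coefficients for the three stages, in order."""
        self.validate_for_fs(fs)
        nyq = fs / 2.0
        hp = sps.butter(self.highpass_order, self.highpass_cutoff_hz / nyq,
                        btype="highpass", output="sos")
        notch = sps.butter(self.notch_order,
                           [self.notch_band_hz[0] / nyq, self.notch_band_hz[1] / nyq],
                           btype="bandstop", output="sos")
        bp = sps.butter(self.bandpass_order,
                        [self.bandpass_band_hz[0] / nyq, self.bandpass_band_hz[1] / nyq],
                        btype="bandpass", output="sos")
        return [hp, notch, bp]

    def frequency_response(self, freqs_hz: Sequence[float], fs: float) -> np.ndarray:
        """Composed magnitude response of the cascade at the given frequencies.

        For the zero-phase (forward–backward) realization the effective
        magnitude is the squared single-pass magnitude.
        """
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        mag = np.ones_like(freqs_hz)
        for sos in self.sos_stages(fs):
            _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs_hz / fs)
            mag *= np.abs(h)
        return mag**2 if self.zero_phase else mag


@dataclass
class WindowSet:
    """Contiguous non-overlapping windows cut from a recording's core segment."""

    subject_id: str
    label: str
    windows: list[np.ndarray] = field(default_factory=list)
    window_len: int = DEFAULT_WINDOW_LEN
    core_fraction: tuple[float, float] = DEFAULT_CORE_FRACTION

    def __len__(self) -> int:
        return len(self.windows)


def minmax_normalize(samples: np.ndarray) -> np.ndarray:
    """Per-channel affine map onto [0, 1]: ``x' = (x - min)/(max - min)``.

    Raises :class:`DegenerateInputError` naming the offending channel if a
    channel is constant (max = min), rather than silently emitting 0.5.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    mins = samples.min(axis=1, keepdims=True)
    maxs = samples.max(axis=1, keepdims=True)
    flat = np.nonzero((maxs - mins).ravel() == 0)[0]
    if flat.size:
        raise DegenerateInputError(
            f"constant channel(s) {flat.tolist()} cannot be min-max normalized")
    return (samples - mins) / (maxs - mins)


def select_core_segment(samples: np.ndarray,
                        core_fraction: tuple[float, float] = DEFAULT_CORE_FRACTION
                        ) -> np.ndarray:
    """Keep samples with indices in ``[floor(lo·T), floor(hi·T))``."""
    lo, hi = core_fraction
    if not 0 <= lo < hi <= 1:
        raise InvalidArgumentError("core_fraction must satisfy 0 ≤ lo < hi ≤ 1")
    samples = np.atleast_2d(np.asarray(samples))
    t = samples.shape[1]
    start = int(np.floor(lo * t))
    stop = int(np.floor(hi * t))
    if stop <= start:
        raise DegenerateInputError(
            f"core segment [{start}, {stop}) of a length-{t} recording is empty")
    return samples[:, start:stop]


def apply_filter_chain(samples: np.ndarray, fs: float,
                       spec: FilterSpec | None = None) -> np.ndarray:
    """Run the high-pass → notch → band-pass cascade on every channel.

    Output length equals input length; each stage is linear time-invariant
    and applied independently per channel (zero-phase by default).
    """
    spec = spec or FilterSpec()
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    max_order = 2 * max(spec.highpass_order, spec.notch_order, spec.bandpass_order)
    if samples.shape[1] <= 3 * max_order:
        raise InvalidArgumentError("recording too short for the filter orders")
    out = samples
    for sos in spec.sos_stages(fs):
        if spec.zero_phase:
            out = sps.sosfiltfilt(sos, out, axis=1)
        else:
            out = sps.sosfilt(sos, out, axis=1)
    return out


def segment_windows(samples: np.ndarray, window_len: int = DEFAULT_WINDOW_LEN,
                    subject_id: str = "", label: str = "",
                    core_fraction: tuple[float, float] = DEFAULT_CORE_FRACTION
                    ) -> WindowSet:
    """Cut ``floor(T/window_len)`` contiguous windows; remainder discarded.

    A segment shorter than one window yields an empty WindowSet (not an
    error).
    """
    if window_len < 1:
        raise InvalidArgumentError("window_len must be ≥ 1")
    samples = np.atleast_2d(np.asarray(samples))
    t = samples.shape[1]
    n_windows = t // window_len
    windows = [samples[:, i * window_len:(i + 1) * window_len].copy()
               for i in range(n_windows)]
    return WindowSet(subject_id=subject_id, label=label, windows=windows,
                     window_len=window_len, core_fraction=core_fraction)


def preprocess_recording(recording: Recording,
                         spec: FilterSpec | None = None,
                         core_fraction: tuple[float, float] = DEFAULT_CORE_FRACTION,
                         window_len: int = DEFAULT_WINDOW_LEN,
                         normalize_first: bool = True,
                         filter_per_window: bool = False) -> WindowSet:
    """Full chain: normalize → core segment → filter → renormalize → window.

    The filter cascade removes DC, so its output is re-normalized per
    channel over the whole core segment (preserving relative amplitude
    across a subject's windows) before being cut into [0, 1]-valued windows
    ready for rendering.  ``filter_per_window=True`` instead filters each
    1-s window independently after cutting.
    """
    spec = spec or FilterSpec()
    x = recording.samples
    if normalize_first:
        x = minmax_normalize(x)
    core = select_core_segment(x, core_fraction)
    if not normalize_first:
        core = minmax_normalize(core)
    if filter_per_window:
        ws = segment_windows(core, window_len, recording.subject_id,
                             recording.label, core_fraction)
        ws.windows = [minmax_normalize(apply_filter_chain(w, recording.fs, spec))
                      for w in ws.windows]
        return ws
    filtered = apply_filter_chain(core, recording.fs, spec)
    filtered = minmax_normalize(filtered)
    return segment_windows(filtered, window_len, recording.subject_id,
                           recording.label, core_fraction)
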
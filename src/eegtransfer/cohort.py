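"""Synthetic multi-subject prefrontal EEG cohorts.

Real few-electrode depression studies record resting-state EEG from the
frontopolar sites Fp1, Fpz and Fp2 at 250 Hz and store each recording as a
plain-text table of microvolt samples.  This module generates a labelled
stand-in cohort with the statistical structure such a study has to cope
with:

* a class effect — depressed subjects show reduced alpha power and an
  elevated theta/alpha ratio in the frontal channels (a configurable
  stand-in for whatever features discriminate in real data, not a clinical
  claim);
* between-subject distribution shift — per-subject random gain, baseline
  offset, noise level and alpha peak frequency, so that a classifier
  trained on some subjects faces a genuinely shifted distribution on a new
  subject;
* 50 Hz mains contamination and a 1/f (pink) background floor.

All randomness is driven by one pseudo-random stream per subject derived
from ``(cohort seed, subject index)``, so cohorts are reproducible and
extensible without perturbing existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidArgumentError

CHANNEL_NAMES: tuple[str, str, str] = ("Fp1", "Fpz", "Fp2")
DEFAULT_FS = 250.0

#: Fixed mixing of the shared (alpha, theta, pink) sources into the three
#: channels.  Neighbouring prefrontal electrodes are strongly correlated, so
#: the rows are similar but not identical.
CHANNEL_MIXING = np.array(
    [
        [1.00, 0.95, 0.90],  # Fp1
        [0.95, 1.00, 0.95],  # Fpz
        [0.90, 0.95, 1.00],  # Fp2
    ]
)

#: Standard deviation of the pink-noise background floor (µV).
PINK_NOISE_SD = 1.0

Label = Literal["healthy", "depressed"]


@dataclass(frozen=True)
class SubjectProfile:
    """Latent parameters of one simulated subject.

    Amplitude parameters are in µV (powers in µV²); ``alpha_peak_hz`` is the
    subject's individual alpha frequency, constrained to the 8–13 Hz band.
    """

    subject_id: str
    label: Label
    gain: float = 1.0
    baseline_offset: float = 0.0
    noise_sd: float = 2.0
    alpha_peak_hz: float = 10.0
    alpha_power: float = 25.0
    theta_power: float = 6.0
    mains_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("healthy", "depressed"):
            raise InvalidArgumentError(f"unknown label {self.label!r}")
        if not self.gain > 0:
            raise InvalidArgumentError("gain must be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be nonnegative")
        if not 8.0 <= self.alpha_peak_hz <= 13.0:
            raise InvalidArgumentError("alpha_peak_hz must lie in [8, 13]")
        if self.alpha_power < 0 or self.theta_power < 0:
            raise InvalidArgumentError("band powers must be nonnegative")
        if self.mains_amplitude < 0:
            raise InvalidArgumentError("mains_amplitude must be nonnegative")


@dataclass
class Recording:
    """One subject's labelled 3-channel EEG time series.

    ``samples`` is a 3×T float array in µV with rows ordered Fp1, Fpz, Fp2.
    """

    subject_id: str
    label: Label
    samples: np.ndarray
    fs: float = DEFAULT_FS
    channels: tuple[str, str, str] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise InvalidArgumentError("samples must be a 3×T matrix")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.samples.shape[1] < self.fs:
            raise InvalidArgumentError("recording must span at least 1 s")
        if tuple(self.channels) != CHANNEL_NAMES:
            raise InvalidArgumentError(f"channels must be {CHANNEL_NAMES}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = max(lo, 0.1)
    hi = min(hi, nyq * 0.99)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC from the noise floor
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject(profile: SubjectProfile, duration_s: float = 60.0,
                     fs: float = DEFAULT_FS) -> Recording:
    """Synthesize one subject's resting-state 3-channel recording.

    The three channels share band-limited alpha (centred at the subject's
    alpha peak), theta (4–7 Hz) and pink-noise sources through a fixed
    mixing matrix, so they are correlated but not identical; white sensor
    noise is independent per channel.  The deterministic structure is

    ``gain·(alpha + theta + pink) + baseline + mains·sin(2π·50·t+φ) + white``

    with band components scaled to the profile's powers (µV²).
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    n = int(np.floor(duration_s * fs))
    if n <= 0:
        raise InvalidArgumentError("duration too short for one sample")

    rng = np.random.default_rng(profile.seed)
    t = np.arange(n) / fs

    f_a = profile.alpha_peak_hz
    alpha = (np.sqrt(profile.alpha_power)
             * _band_limited_noise(rng, n, fs, f_a - 1.0, f_a + 1.0)
             if profile.alpha_power > 0 else np.zeros(n))
    theta = (np.sqrt(profile.theta_power)
             * _band_limited_noise(rng, n, fs, 4.0, 7.0)
             if profile.theta_power > 0 else np.zeros(n))
    pink = PINK_NOISE_SD * _pink_noise(rng, n)
    # With every stochastic component disabled the output must be exactly
    # the baseline, so the pink floor is tied to noise_sd being nonzero.
    if profile.noise_sd == 0 and profile.alpha_power == 0 and profile.theta_power == 0:
        pink = np.zeros(n)

    sources = np.stack([alpha, theta, pink])            # 3 sources × T
    oscillatory = CHANNEL_MIXING @ sources              # 3 channels × T

    phase = rng.uniform(0, 2 * np.pi)
    mains = profile.mains_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)
    white = profile.noise_sd * rng.standard_normal((3, n))

    samples = (profile.gain * oscillatory
               + profile.baseline_offset
               + mains[None, :]
               + white)
    return Recording(subject_id=profile.subject_id, label=profile.label,
                     samples=samples, fs=fs)


def _draw_profile(subject_id: str, label: Label, class_effect: float,
                  shift_sd: float, seed: int) -> SubjectProfile:
    """Draw one subject's latent parameters.

    Band powers are log-normal with between-subject log-sd 0.3; the
    depressed class mean is displaced by ``class_effect`` standardized
    units (down for alpha, up for theta).  Gain, baseline, noise level and
    alpha peak get per-subject dispersion scaled by ``shift_sd``.
    """
    rng = np.random.default_rng(seed)
    sign = -1.0 if label == "depressed" else 0.0
    log_sd = 0.3
    alpha_power = float(np.exp(rng.normal(np.log(25.0) + sign * class_effect * log_sd, log_sd)))
    theta_power = float(np.exp(rng.normal(np.log(6.0) - sign * class_effect * log_sd, log_sd)))
    return SubjectProfile(
        subject_id=subject_id,
        label=label,
        gain=float(np.exp(rng.normal(0.0, 0.25 * shift_sd))),
        baseline_offset=float(rng.normal(0.0, 10.0 * shift_sd)),
        noise_sd=float(2.0 * np.exp(rng.normal(0.0, 0.5 * shift_sd))),
        alpha_peak_hz=float(np.clip(10.0 + rng.normal(0.0, 1.5 * shift_sd), 8.0, 13.0)),
        alpha_power=alpha_power,
        theta_power=theta_power,
        mains_amplitude=float(rng.uniform(0.5, 3.0)),
        seed=seed,
    )


def _subject_seed(cohort_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(n_healthy: int, n_depressed: int, class_effect: float = 1.0,
                    shift_sd: float = 0.3, seed: int = 0,
                    duration_s: float = 60.0,
                    fs: float = DEFAULT_FS) -> list[Recording]:
    """Generate a labelled cohort with class structure and subject shift.

    Healthy subjects come first (``H00…``), then depressed (``D00…``).
    ``class_effect`` is the standardized mean shift between the two
    classes' band-power distributions; ``class_effect=0`` makes the classes
    statistically identical.  ``shift_sd`` scales the between-subject
    dispersion of gain, baseline, noise level and alpha peak.
    """
    if n_healthy < 0 or n_depressed < 0:
        raise InvalidArgumentError("subject counts must be nonnegative")
    recordings: list[Recording] = []
    labels: list[Label] = (["healthy"] * n_healthy) + (["depressed"] * n_depressed)
    n_h = 0
    n_d = 0
    for idx, label in enumerate(labels):
        if label == "healthy":
            sid = f"H{n_h:02d}"
            n_h += 1
        else:
            sid = f"D{n_d:02d}"
            n_d += 1
        profile = _draw_profile(sid, label, class_effect, shift_sd,
                                _subject_seed(seed, idx))
        recordings.append(generate_subject(profile, duration_s=duration_s, fs=fs))
    return recordings


# ---------------------------------------------------------------------------
# Plain-text I/O: per-recording whitespace-delimited columns Fp1 Fpz Fp2 plus
# a cohort manifest CSV (subject_id, label, path, fs).
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path,
                    header: bool = True) -> None:
    """Write one recording as text columns (one row per sample, µV)."""
    path = Path(path)
    hdr = "\t".join(recording.channels) if header else ""
    np.savetxt(path, recording.samples.T, fmt="%.6f", delimiter="\t",
               header=hdr, comments="")


def read_recording(path: str | Path, subject_id: str, label: Label,
                   fs: float = DEFAULT_FS) -> Recording:
    """Read a plain-text recording (columns Fp1, Fpz, Fp2).

    Accepts whitespace- or comma-delimited numeric columns with an optional
    single header line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    skip = 0
    try:
        [float(tok) for tok in first.replace(",", " ").split()]
    except ValueError:
        skip = 1
    data = np.loadtxt(path, delimiter=delimiter, skiprows=skip, ndmin=2)
    if data.shape[1] != 3:
        raise InvalidArgumentError(
            f"{path} has {data.shape[1]} columns, expected 3 (Fp1, Fpz, Fp2)")
    return Recording(subject_id=subject_id, label=label, samples=data.T, fs=fs)


def write_cohort(recordings: Sequence[Recording], outdir: str | Path,
                 manifest_name: str = "manifest.csv") -> Path:
    """Write every recording as text plus a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.txt"
        write_recording(rec, outdir / fname)
        rows.append({"subject_id": rec.subject_id, "label": rec.label,
                     "path": fname, "fs": rec.fs})
    manifest = outdir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    return [read_recording(base / row.path, row.subject_id, row.label, fs=row.fs)
            for row in df.itertuples()]
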
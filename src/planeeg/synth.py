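"""Seeded synthetic surface-electrode recordings.

Generates signals with the statistical structure the analysis pipeline
assumes of planarian surface-EEG: a 1/f^x power-law background, optional
band-limited oscillatory components, large brief myogenic-like spike
transients, and power-line contamination at 50 Hz with harmonic and
subharmonic components (25, 100 Hz).  All randomness flows from one seed,
so identical configurations reproduce bit-identical recordings.

Amplitudes are expressed in multiples of the background standard deviation
rather than microvolts: the physiological amplitude scale of planarian
surface recordings is not a settled quantity, and the analysis pipeline is
scale-invariant throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Recording, write_recording

__all__ = [
    "SynthesisConfig",
    "generate_colored_noise",
    "generate_oscillation",
    "inject_artifacts",
    "simulate_group_study",
    "write_study",
]

#: Condition-wise aperiodic exponents emulating the study groups: live
#: planarians in darkness / under light, the dead-control preparation
#: (dominated by low-frequency setup noise, hence the steep 2.72), and the
#: decapitated follow-up groups.
DEFAULT_EXPONENTS = {
    "darkness": 1.23,
    "light": 1.31,
    "control": 2.72,
    "decapitated_darkness": 1.32,
    "decapitated_light": 1.48,
}

#: Power-line fundamental plus first harmonic and subharmonic, relative
#: amplitudes chosen so the 50 Hz fundamental matches the background SD.
DEFAULT_LINE_NOISE = ((25.0, 0.5), (50.0, 1.0), (100.0, 0.5))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_colored_noise(n_samples: int, fs: float, exponent: float,
                           seed=None) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance.

    White Gaussian noise is shaped in the frequency domain: the DFT
    amplitude at frequency f is scaled by f**(-exponent/2) (the DC bin is
    zeroed), the result inverted and standardized to zero mean and unit
    sample variance.  ``exponent=0`` returns plain white noise.
    """
    n_samples = int(n_samples)
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if not np.isfinite(exponent) or exponent < 0:
        raise ValueError("exponent must be finite and non-negative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = _as_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def generate_oscillation(n_samples: int, fs: float, center: float,
                         bandwidth: float, seed=None) -> np.ndarray:
    """Band-limited Gaussian oscillation, unit variance.

    White noise shaped by a Gaussian spectral envelope centered on
    ``center`` with standard deviation ``bandwidth / 2`` — a stochastic
    narrow-band rhythm rather than a phase-locked sinusoid.
    """
    if not 0 < center < fs / 2:
        raise ValueError("oscillation center must lie below the Nyquist rate")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    rng = _as_rng(seed)
    white = rng.standard_normal(int(n_samples))
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(int(n_samples), d=1.0 / fs)
    envelope = np.exp(-0.5 * ((freqs - center) / (bandwidth / 2.0)) ** 2)
    envelope[0] = 0.0
    x = np.fft.irfft(spec * envelope, n=int(n_samples))
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _raised_cosine(fs: float, half_width: float = 0.040) -> np.ndarray:
    """Unit-peak raised-cosine transient of total duration 2*half_width."""
    n = int(round(2 * half_width * fs)) | 1   # odd length, peak on a sample
    t = np.arange(n) - n // 2
    return 0.5 * (1.0 + np.cos(np.pi * t / (n // 2 + 1)))


def inject_artifacts(signal: np.ndarray, fs: float, spike_rate: float = 0.0,
                     spike_amplitude: float = 0.0, line_noise=(),
                     seed=None) -> np.ndarray:
    """Add myogenic-like spike transients and power-line tones to a signal.

    Parameters
    ----------
    spike_rate : float
        Expected spike events per minute; the realized count is Poisson.
    spike_amplitude : float
        Peak spike magnitude in multiples of the input's standard
        deviation; spike polarity is random.
    line_noise : sequence of (frequency Hz, relative amplitude)
        Sinusoids with random phase; amplitude is relative to the input SD
        (or absolute if the input has zero variance, e.g. a silent trace).

    With ``spike_rate=0`` and no line noise the input is returned unchanged
    (as a copy).
    """
    signal = np.asarray(signal, dtype=float)
    if spike_rate < 0:
        raise ValueError("spike_rate must be non-negative")
    for f, _ in line_noise:
        if f >= fs / 2:
            raise ValueError(f"line-noise frequency {f} Hz is at or above Nyquist")
    rng = _as_rng(seed)
    out = signal.copy()
    sd = signal.std()
    ref = sd if sd > 0 else 1.0

    if spike_rate > 0 and spike_amplitude != 0:
        kernel = _raised_cosine(fs)
        n_events = rng.poisson(spike_rate * len(signal) / fs / 60.0)
        half = len(kernel) // 2
        if len(signal) > 2 * half:
            centers = rng.integers(half, len(signal) - half, size=n_events)
            signs = rng.choice([-1.0, 1.0], size=n_events)
            for c, s in zip(centers, signs):
                out[c - half: c + half + 1] += s * spike_amplitude * ref * kernel

    t = np.arange(len(signal)) / fs
    for f, amp in line_noise:
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * ref * np.sin(2 * np.pi * f * t + phase)
    return out


@dataclass
class SynthesisConfig:
    """Study-level synthesis settings.

    ``n_datasets_per_group`` may be one integer for all groups or a mapping
    from group label to count.  ``exponent_per_group`` maps condition label
    to the target aperiodic exponent of the 1/f^x background.
    ``oscillations`` is a list of (center Hz, bandwidth Hz, amplitude
    relative to background SD) added to every dataset.
    """

    n_datasets_per_group: object = 10
    duration: float = 600.0
    fs: float = 500.0
    n_channels: int = 1
    exponent_per_group: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPONENTS))
    oscillations: tuple = ()
    spike_rate: float = 0.5
    spike_amplitude: float = 20.0
    line_noise: tuple = DEFAULT_LINE_NOISE
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0 or self.n_channels < 1:
            raise ValueError("fs, duration and n_channels must be positive")
        for g, x in self.exponent_per_group.items():
            if not np.isfinite(x) or x < 0:
                raise ValueError(f"exponent for group {g!r} must be finite and >= 0")
        top = [f for f, _ in self.line_noise] + [c for c, _, _ in self.oscillations]
        if top and self.fs <= 2 * max(top):
            raise ValueError("fs must exceed twice the highest injected frequency")

    def n_for(self, group: str) -> int:
        if isinstance(self.n_datasets_per_group, dict):
            return int(self.n_datasets_per_group[group])
        return int(self.n_datasets_per_group)


def simulate_group_study(config: SynthesisConfig) -> list:
    """Generate a full between-groups study; returns a list of Recording.

    Each dataset is the group's 1/f^x background plus the configured
    oscillations and artifacts, one independent child seed per dataset
    (derived from ``config.seed``), so the whole study is reproducible from
    the single study seed.
    """
    groups = list(config.exponent_per_group)
    if len(groups) < 2:
        raise ValueError("a group study needs at least two groups")
    for g in groups:
        if config.n_for(g) < 2:
            raise ValueError(f"group {g!r} needs at least 2 datasets")

    n_samples = int(round(config.duration * config.fs))
    total = sum(config.n_for(g) for g in groups)
    children = np.random.SeedSequence(config.seed).spawn(total)
    recordings, ids = [], set()
    k = 0
    for group in groups:
        x = config.exponent_per_group[group]
        for i in range(config.n_for(group)):
            rng = np.random.default_rng(children[k])
            chans = []
            for _ in range(config.n_channels):
                sig = generate_colored_noise(n_samples, config.fs, x, rng)
                for center, bw, amp in config.oscillations:
                    sig = sig + amp * generate_oscillation(
                        n_samples, config.fs, center, bw, rng)
                sig = inject_artifacts(
                    sig, config.fs, config.spike_rate, config.spike_amplitude,
                    config.line_noise, rng)
                chans.append(sig)
            ds_id = f"{group}_{i:02d}"
            if ds_id in ids:
                raise ValueError(f"duplicate dataset identifier {ds_id!r}")
            ids.add(ds_id)
            recordings.append(Recording(
                data=np.vstack(chans), fs=config.fs, group=group,
                source="synthetic",
                meta={
                    "dataset_id": ds_id, "group": group, "exponent": x,
                    "study_seed": config.seed, "dataset_index": k,
                    "spike_rate": config.spike_rate,
                    "spike_amplitude": config.spike_amplitude,
                    "line_noise": [list(p) for p in config.line_noise],
                    "oscillations": [list(o) for o in config.oscillations],
                },
            ))
            k += 1
    return recordings


def write_study(recordings, outdir, format: str = "edf") -> Path:
    """Write a generated study to disk plus a JSON manifest.

    The manifest maps each filename to its group label and generation
    metadata; it is what :func:`planeeg.pipeline.run_study` consumes when
    running from files.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = {"edf": ".edf", "text": ".txt"}[format]
    manifest = {}
    for rec in recordings:
        ds_id = rec.meta.get("dataset_id", f"dataset_{len(manifest):03d}")
        fname = ds_id + suffix
        write_recording(rec, outdir / fname, format=format)
        manifest[fname] = {
            "group": rec.group,
            "fs": rec.fs,
            **{k: v for k, v in rec.meta.items() if k != "group"},
        }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
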
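"""Synthetic two-class multichannel oscillatory trials with planted structure.

Every channel carries 1/f^gamma coloured noise; a designated subset of
informative channels additionally carries band-limited oscillatory activity
(band-passed Gaussian noise, so phase varies trial to trial) whose power is
modulated between the two classes: band power is scaled by (1 + effect) for
one class and (1 - effect) for the other, with the favoured class
alternating across bands.  This emulates the event-related
desynchronisation / synchronisation band-power contrasts that motor-imagery
classifiers exploit, without attempting real cortical waveform morphology,
artifacts or electrode-grid spatial correlation.

Ground truth (which channels/bands are informative and which class gets the
power boost in each band) is returned in a manifest so recovery of the
planted structure can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .containers import TrialTensor

__all__ = ["SynthConfig", "Fixture", "generate", "make_fixture"]

_DEFAULT_INFORMATIVE = (3, 10, 18, 21, 36, 44, 52, 59)


@dataclass
class SynthConfig:
    """Generator settings.

    ``effect_size`` is the relative band-power modulation between classes
    (power ratio (1+e)/(1-e) on an informative band); ``amplitude`` is the
    oscillation's standard deviation relative to the unit-variance noise
    floor; ``amplitude_jitter`` is the sigma of a lognormal per-trial
    amplitude factor emulating trial-to-trial ERD/ERS variability.
    """

    n_trials_per_class: int = 100
    n_channels: int = 64
    informative_channels: tuple[int, ...] = _DEFAULT_INFORMATIVE
    informative_bands: tuple[tuple[float, float], ...] = ((8.0, 12.0), (18.0, 26.0))
    effect_size: float = 0.8
    amplitude: float = 0.2
    amplitude_jitter: float = 0.3
    fs: float = 100.0
    duration: float = 3.0
    noise_exponent: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1 or self.n_channels < 1:
            raise ValueError("need at least one trial per class and one channel")
        ch = tuple(int(c) for c in self.informative_channels)
        if any(c < 0 or c >= self.n_channels for c in ch):
            raise ValueError("informative_channels must index into [0, n_channels)")
        self.informative_channels = ch
        for lo, hi in self.informative_bands:
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError("bands must satisfy 0 < f_lo < f_hi < fs/2")
        if self.effect_size < 0 or self.effect_size >= 1:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.effect_size > 0 and len(ch) == 0:
            raise ValueError(
                "a nonzero effect_size requires at least one informative channel"
            )
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _colored_noise(rng: np.random.Generator, shape: tuple, n: int, gamma: float) -> np.ndarray:
    """Unit-variance 1/f^gamma noise along the last axis (length n)."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.empty_like(f)
    scale[0] = 0.0  # no DC component
    scale[1:] = f[1:] ** (-gamma / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_noise(
    rng: np.random.Generator, shape: tuple, n: int, lo: float, hi: float, fs: float
) -> np.ndarray:
    """Unit-variance band-limited oscillation: band-passed white noise."""
    # pad so the zero-phase band-pass transient stays outside the trial
    pad = n
    raw = rng.standard_normal(shape + (n + 2 * pad,))
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, raw, axis=-1)[..., pad : pad + n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Draw a labelled trial tensor plus the planted-truth manifest.

    Returns ``(TrialTensor, manifest)`` where the manifest records the
    informative channels, the bands, and which class's band power is scaled
    up in each band (band b favours class ``(-1)**b`` flipped: band 0 boosts
    class +1, band 1 boosts class -1, and so on).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_per, n_ch, n_s = cfg.n_trials_per_class, cfg.n_channels, cfg.n_samples
    n_trials = 2 * n_per

    labels = np.concatenate([np.ones(n_per, dtype=np.int64), -np.ones(n_per, dtype=np.int64)])
    data = _colored_noise(rng, (n_trials, n_ch), n_s, cfg.noise_exponent)

    band_signs = []
    info = np.asarray(cfg.informative_channels, dtype=np.intp)
    if info.size and (cfg.effect_size > 0 or cfg.amplitude > 0):
        for b, (lo, hi) in enumerate(cfg.informative_bands):
            boosted_class = 1 if b % 2 == 0 else -1
            band_signs.append(boosted_class)
            osc = _band_noise(rng, (n_trials, info.size), n_s, lo, hi, cfg.fs)
            # power x(1+e) for the boosted class, x(1-e) for the other
            power_gain = np.where(
                labels == boosted_class, 1.0 + cfg.effect_size, 1.0 - cfg.effect_size
            )
            jitter = np.exp(cfg.amplitude_jitter * rng.standard_normal(n_trials))
            amp = cfg.amplitude * np.sqrt(power_gain) * jitter
            data[:, info, :] += amp[:, None, None] * osc

    order = rng.permutation(n_trials)
    tensor = TrialTensor(data[order], labels[order], cfg.fs)
    manifest = {
        "informative_channels": [int(c) for c in cfg.informative_channels],
        "informative_bands": [[float(lo), float(hi)] for lo, hi in cfg.informative_bands],
        "band_boosted_class": band_signs,
        "effect_size": cfg.effect_size,
        "amplitude": cfg.amplitude,
        "amplitude_jitter": cfg.amplitude_jitter,
        "noise_exponent": cfg.noise_exponent,
        "fs": cfg.fs,
        "duration": cfg.duration,
        "n_trials": n_trials,
        "seed": cfg.seed,
    }
    return tensor, manifest


class Fixture(NamedTuple):
    """A generated fixture: training tensor, optional test tensor, truth."""

    train: TrialTensor
    test: TrialTensor | None
    manifest: dict


def make_fixture(kind: str, seed: int | None = 0) -> Fixture:
    """Canned fixtures for tests and examples.

    ``"tiny"``: 40 trials x 8 channels x 1 s at 100 Hz, two informative
    channels, one mu band — fast enough for unit tests.  ``"benchmark"``:
    278 training + 100 test trials x 64 channels x 3 s at 100 Hz, the layout
    of a full public ECoG motor-imagery benchmark recording.
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny":
        cfg = SynthConfig(
            n_trials_per_class=20,
            n_channels=8,
            informative_channels=(1, 3),
            informative_bands=((8.0, 12.0),),
            duration=1.0,
        )
        tensor, manifest = generate(cfg, rng)
        return Fixture(tensor, None, manifest)
    if kind == "benchmark":
        cfg = SynthConfig(n_trials_per_class=139, n_channels=64, duration=3.0)
        train, manifest = generate(cfg, rng)
        test_cfg = SynthConfig(n_trials_per_class=50, n_channels=64, duration=3.0)
        test, _ = generate(test_cfg, rng)
        return Fixture(train, test, manifest)
    raise ValueError(f"unknown fixture kind {kind!r}; use 'tiny' or 'benchmark'")
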
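"""Seeded generator of 2-s single-lead ECG fragments with shockable-rhythm morphologies.

Four classes are emulated:

* **C1 (VFL, ventricular flutter)** — fast near-sinusoidal waves; a single
  dominant oscillation with a small second harmonic, fundamental drawn in
  4–6 Hz.
* **C2 (VF, ventricular fibrillation)** — chaotic irregular waves; a sum of
  several sinusoids with frequencies scattered over 3–8 Hz, random phases and
  slowly drifting amplitudes, so no stable period exists.
* **C3 (VTTdP, torsade de pointes)** — a wide-complex pulse train (3–5 Hz)
  whose amplitude envelope is sinusoidally modulated at 0.2–0.5 Hz and whose
  polarity alternates about the isoelectric line (the characteristic
  "twisting" of the QRS axis).
* **C4 (VTHR, high-rate monomorphic VT)** — a strictly periodic wide-complex
  pulse train at 2.5–4 Hz with constant amplitude (rapid, regular ventricular
  QRS complexes).

The wide "QRS" lobe is a Gaussian-derivative pulse: it mimics a ventricular
complex visually and spectrally without modelling P/T waves, which these
rhythms lack.  This is a morphology emulator, not a physiologically validated
ECG model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from shockscale.types import ECGFragment

#: Valid rhythm class labels, in canonical order.
CLASS_LABELS: tuple[str, ...] = ("C1", "C2", "C3", "C4")

#: Human-readable rhythm names keyed by class label.
CLASS_NAMES: dict[str, str] = {
    "C1": "ventricular flutter (VFL)",
    "C2": "ventricular fibrillation (VF)",
    "C3": "torsade de pointes (VTTdP)",
    "C4": "high-rate ventricular tachycardia (VTHR)",
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic fragment generator.

    Rate ranges are (low, high) in Hz; a degenerate range like ``(3, 3)``
    pins the draw.  ``seed`` fully determines the output: every fragment uses
    its own RNG stream derived from ``(seed, class, index)``, so generating
    more fragments never perturbs existing ones.
    """

    fs: float = 250.0
    duration: float = 2.0
    noise_sd: float = 0.05
    amplitude: float = 1.0
    seed: int = 0
    c1_rate: tuple[float, float] = (4.0, 6.0)
    c2_band: tuple[float, float] = (3.0, 8.0)
    c2_components: int = 6
    c2_drift_hz: float = 0.4
    c3_rate: tuple[float, float] = (3.0, 5.0)
    c3_mod: tuple[float, float] = (0.2, 0.5)
    c3_depth: float = 0.8
    c4_rate: tuple[float, float] = (2.5, 4.0)
    c4_jitter: float = 0.01
    qrs_width_s: float = 0.04

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("c1_rate", "c2_band", "c3_rate", "c3_mod", "c4_rate"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if not 0.0 <= self.c3_depth <= 1.0:
            raise ValueError("c3_depth must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _fragment_rng(cfg: SynthConfig, cls: str, index: int) -> np.random.Generator:
    # One named stream per (class, index): insertion order never changes
    # already-generated fragments.
    return np.random.default_rng([int(cfg.seed), CLASS_LABELS.index(cls), int(index)])


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _pulse_train(
    t: np.ndarray, rate: float, phase: float, width: float, jitter_offsets: np.ndarray
) -> np.ndarray:
    """Sum of unit-peak Gaussian-derivative lobes at times k/rate + phase (+ jitter)."""
    out = np.zeros_like(t)
    t_end = t[-1]
    n_pulses = int(np.ceil((t_end + 4 * width) * rate)) + 2
    centers = phase + np.arange(-1, n_pulses) / rate
    if len(jitter_offsets):
        pad = np.zeros(max(0, len(centers) - len(jitter_offsets)))
        centers = centers + np.concatenate([jitter_offsets, pad])[: len(centers)]
    # Gaussian first derivative, normalised to peak amplitude 1 (peak at |u| = width).
    peak = width * np.exp(-0.5)
    for c in centers:
        u = t - c
        out += -(u) * np.exp(-(u**2) / (2 * width**2)) / peak
    return out


def _make_c1(t: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    f0 = _uniform(rng, cfg.c1_rate)
    phase = rng.uniform(0, 2 * np.pi)
    # near-sinusoid: dominant fundamental plus a faint second harmonic
    x = 0.9 * np.sin(2 * np.pi * f0 * t + phase) + 0.1 * np.sin(4 * np.pi * f0 * t + 2 * phase)
    return x


def _make_c2(t: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = max(5, int(cfg.c2_components))
    freqs = rng.uniform(*cfg.c2_band, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    base_amp = rng.uniform(0.5, 1.0, size=n)
    drift_phase = rng.uniform(0, 2 * np.pi, size=n)
    x = np.zeros_like(t)
    for k in range(n):
        # slow independent amplitude drift destroys any stable period
        drift = 1.0 + 0.5 * np.sin(2 * np.pi * cfg.c2_drift_hz * t + drift_phase[k])
        x += base_amp[k] * drift * np.sin(2 * np.pi * freqs[k] * t + phases[k])
    # normalise worst-case sum of component amplitudes to 1
    x /= np.sum(base_amp * 1.5)
    return x


def _make_c3(t: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    rate = _uniform(rng, cfg.c3_rate)
    f_mod = _uniform(rng, cfg.c3_mod)
    phase = rng.uniform(0, 1.0 / rate)
    pulses = _pulse_train(t, rate, phase, cfg.qrs_width_s, np.zeros(0))
    # amplitude envelope swings between (1 - depth) and 1 at the modulation rate
    envelope = 1.0 - 0.5 * cfg.c3_depth * (1.0 - np.cos(2 * np.pi * f_mod * t))
    # polarity flips at the envelope minima: the QRS axis "twists" about the
    # isoline exactly where the amplitude pinches
    polarity = np.where(np.cos(np.pi * f_mod * t) >= 0, 1.0, -1.0)
    return pulses * envelope * polarity


def _make_c4(t: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    rate = _uniform(rng, cfg.c4_rate)
    phase = rng.uniform(0, 1.0 / rate)
    n_pulses = int(np.ceil((t[-1] + 1) * rate)) + 4
    jitter = rng.normal(0.0, cfg.c4_jitter / rate, size=n_pulses) if cfg.c4_jitter > 0 else np.zeros(n_pulses)
    return _pulse_train(t, rate, phase, cfg.qrs_width_s, jitter)


_MORPHOLOGIES = {"C1": _make_c1, "C2": _make_c2, "C3": _make_c3, "C4": _make_c4}


def generate_fragment(cls: str, cfg: SynthConfig, index: int = 0) -> ECGFragment:
    """Generate one fragment of class ``cls``.

    Deterministic given ``(cls, cfg.seed, index)``.  Additive white Gaussian
    noise of standard deviation ``cfg.noise_sd`` (mV) is applied after the
    morphology is scaled to ``cfg.amplitude``.

    Raises
    ------
    ValueError
        If ``cls`` is not one of :data:`CLASS_LABELS`.
    """
    if cls not in _MORPHOLOGIES:
        raise ValueError(f"unknown class label {cls!r}; valid labels are {', '.join(CLASS_LABELS)}")
    rng = _fragment_rng(cfg, cls, index)
    t = np.arange(cfg.n_samples) / cfg.fs
    x = cfg.amplitude * _MORPHOLOGIES[cls](t, cfg, rng)
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=x.shape)
    return ECGFragment(samples=x, fs=cfg.fs, label=cls, id=f"{cls}-{index:05d}")


def generate_dataset(counts: dict[str, int], cfg: SynthConfig) -> list[ECGFragment]:
    """Generate ``counts[c]`` fragments per class, class-blocked then index-ordered.

    Ids are unique and the output is fully determined by ``(counts, cfg)``.
    """
    for cls, n in counts.items():
        if cls not in CLASS_LABELS:
            raise ValueError(f"unknown class label {cls!r}; valid labels are {', '.join(CLASS_LABELS)}")
        if n < 0:
            raise ValueError(f"count for {cls} must be non-negative")
    out: list[ECGFragment] = []
    for cls in CLASS_LABELS:
        for i in range(counts.get(cls, 0)):
            out.append(generate_fragment(cls, cfg, i))
    return out
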
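"""Forward simulation of multichannel SSVEP epochs.

Each simulated trial is a sum of

* a stimulation-rate sinusoid (phase-locked across trials) projected
  through a parieto-occipital topography,
* in regular conditions only, a regularity-rate sinusoid whose trial
  phase is drawn from a von Mises distribution — the concentration kappa
  controls inter-trial phase clustering and maps analytically onto the
  expected Cosine Similarity index via ``expected_cs``,
* spatially correlated 1/f^beta background noise (generated in the
  frequency domain for exact spectral control, then colored by the
  Cholesky factor of the channel covariance),
* a posterior alpha rhythm with random phase, and
* optional ocular blink transients on the EOG channels, for exercising
  artifact rejection.

No realistic head-model (BEM/FEM) forward computation is attempted; the
fixed Gaussian-blob topographies stand in for the parieto-occipital
response distributions seen in real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .design import Condition, ExperimentSpec, StimulusSequence
from .epochs import EpochSet, default_channel_names, montage_positions

__all__ = [
    "ForwardModel",
    "SimulationConfig",
    "simulate_trial",
    "simulate_experiment",
    "expected_cs",
    "condition_presets",
]


def expected_cs(kappa: float, n: int) -> float:
    """Expected Cosine Similarity under independent von Mises trial phases.

    For phases theta_i ~ von Mises(mu, kappa), E[cos(theta_i - theta_j)]
    = (I1(kappa)/I0(kappa))^2 for i != j, which is the expectation of the
    pairwise CS statistic regardless of the trial count n (n only sets
    the variance).  kappa = 0 gives 0 (uniform phases), kappa -> inf
    gives 1 (perfect clustering).
    """
    if n < 2:
        raise ValueError("CS needs at least 2 trials")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if np.isinf(kappa):
        return 1.0
    r = i1e(kappa) / i0e(kappa)  # exponentially-scaled ratio is stable
    return float(r * r)


def _gaussian_topography(pos: np.ndarray, center: np.ndarray,
                         scale: float) -> np.ndarray:
    """Unit-norm channel vector falling off with distance from a scalp point."""
    w = np.zeros(len(pos))
    ok = ~np.isnan(pos).any(axis=1)
    d2 = np.sum((pos[ok] - center) ** 2, axis=1)
    w[ok] = np.exp(-d2 / (2.0 * scale**2))
    return w / np.linalg.norm(w)


@dataclass
class ForwardModel:
    """Channel topographies and noise spatial covariance for the simulator."""

    ch_names: list[str]
    ch_types: list[str]
    topo_stim: np.ndarray
    topo_reg: np.ndarray
    topo_alpha: np.ndarray
    noise_cov: np.ndarray  # symmetric PD, channels x channels

    def __post_init__(self):
        for name in ("topo_stim", "topo_reg", "topo_alpha"):
            v = getattr(self, name)
            if not np.isclose(np.linalg.norm(v), 1.0):
                raise ValueError(f"{name} must be unit norm")
        c = self.noise_cov
        if not np.allclose(c, c.T):
            raise ValueError("noise covariance must be symmetric")
        try:
            self._chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            raise ValueError("noise covariance must be positive definite") from None

    @classmethod
    def default(cls, ch_names=None, ch_types=None, smoothness: float = 0.06,
                montage: str = "biosemi64") -> "ForwardModel":
        """Parieto-occipital sources over a spatially smooth noise field.

        ``smoothness`` (meters) is the length scale of the squared-
        exponential channel covariance; EOG channels carry independent
        unit-variance noise.
        """
        if ch_names is None:
            ch_names, ch_types = default_channel_names()
        pos = montage_positions(ch_names, montage)
        scalp = ~np.isnan(pos).any(axis=1)

        def at(label, fallback):
            return pos[ch_names.index(label)] if label in ch_names else fallback

        topo_stim = _gaussian_topography(pos, at("Oz", [0, -0.09, 0.0]), 0.045)
        topo_reg = _gaussian_topography(pos, at("POz", [0, -0.08, 0.03]), 0.05)
        topo_alpha = _gaussian_topography(pos, at("Pz", [0, -0.05, 0.07]), 0.06)

        n = len(ch_names)
        cov = np.eye(n)
        p = pos[scalp]
        d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
        block = np.exp(-d2 / (2.0 * smoothness**2))
        cov[np.ix_(scalp, scalp)] = block + 0.1 * np.eye(len(p))
        return cls(list(ch_names), list(ch_types), topo_stim, topo_reg,
                   topo_alpha, cov)


def condition_presets(conditions, f_reg: float) -> tuple[dict, dict]:
    """Default (amp_reg, kappa) per condition cell.

    Mirrors the empirically observed ordering — neutral above angry,
    high above low variability, nothing at the regularity rate in
    irregular streams — without being calibrated to any reported value.
    """
    kappa_base = {"neutral": 1.2, "angry": 0.8, "irregular": 0.0}
    amp = {}
    kappa = {}
    for cond in conditions:
        k = kappa_base[cond.regularity]
        if cond.variability == "low":
            k *= 0.7
        amp[cond.label] = 0.0 if cond.regularity == "irregular" else 0.8
        kappa[cond.label] = k
    return amp, kappa


@dataclass
class SimulationConfig:
    """All tunable knobs of the epoch simulator (amplitudes in microvolts)."""

    f_stim: float
    f_reg: float
    sampling_rate: float = 256.0
    amp_stim: float = 1.0
    amp_reg: dict = field(default_factory=dict)  # condition label -> uV
    kappa: dict = field(default_factory=dict)  # condition label -> von Mises kappa
    phase_mu: float = 0.0  # mean regularity phase (stimulus-locked)
    phase_stim: float = 0.0
    noise_exponent: float = 1.0  # 1/f^beta slope
    noise_scale: float = 1.0  # uV RMS per channel before spatial coloring
    alpha_amp: float = 0.5
    alpha_freq: float = 10.0
    blink_rate: float = 0.0  # events per minute on EOG
    blink_amp: float = 300.0
    blink_leakage: float = 0.1

    def __post_init__(self):
        if not np.isclose(self.f_reg * 3, self.f_stim):
            raise ValueError("f_reg must be f_stim / 3")
        for label, k in self.kappa.items():
            if k < 0:
                raise ValueError(f"kappa < 0 for {label}")

    @classmethod
    def for_spec(cls, spec: ExperimentSpec, **overrides) -> "SimulationConfig":
        amp, kappa = condition_presets(spec.conditions, spec.regularity_rate)
        kw = dict(
            f_stim=spec.stimulation_rate,
            f_reg=spec.regularity_rate,
            amp_reg=amp,
            kappa=kappa,
        )
        kw.update(overrides)
        return cls(**kw)


def _one_over_f_noise(n_channels: int, n_samples: int, beta: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum 1/f^beta, per channel."""
    n_freq = n_samples // 2 + 1
    f = np.arange(n_freq, dtype=float)
    gain = np.zeros(n_freq)
    gain[1:] = f[1:] ** (-beta / 2.0)
    z = rng.standard_normal((n_channels, n_freq)) + 1j * rng.standard_normal(
        (n_channels, n_freq)
    )
    x = np.fft.irfft(z * gain, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def _blink_waveform(n_samples: int, sfreq: float) -> np.ndarray:
    n = int(round(0.4 * sfreq))  # 400 ms raised cosine
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))


def simulate_trial(sequence: StimulusSequence, model: ForwardModel,
                   config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One epoch (channels x samples) for the sequence's condition."""
    label = sequence.condition.label
    regular = sequence.condition.regularity != "irregular"
    if regular and (label not in config.amp_reg or label not in config.kappa):
        raise ValueError(f"no amplitude/kappa configured for condition {label}")

    fs = config.sampling_rate
    n_cycles = len(sequence.cycles)
    duration = n_cycles / config.f_stim  # seconds of RSVP stream
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    x = np.zeros((len(model.ch_names), n_samples))

    if config.amp_stim:
        x += config.amp_stim * np.outer(
            model.topo_stim, np.sin(2 * np.pi * config.f_stim * t + config.phase_stim)
        )
    amp_reg = config.amp_reg.get(label, 0.0)
    if regular and amp_reg:
        kappa = config.kappa[label]
        if np.isinf(kappa):
            theta = config.phase_mu
        elif kappa == 0:
            theta = rng.uniform(-np.pi, np.pi)
        else:
            theta = rng.vonmises(config.phase_mu, kappa)
        x += amp_reg * np.outer(
            model.topo_reg, np.sin(2 * np.pi * config.f_reg * t + theta)
        )
    if config.noise_scale:
        noise = _one_over_f_noise(
            len(model.ch_names), n_samples, config.noise_exponent, rng
        )
        x += config.noise_scale * (model._chol @ noise)
    if config.alpha_amp:
        phi = rng.uniform(-np.pi, np.pi)
        x += config.alpha_amp * np.outer(
            model.topo_alpha, np.sin(2 * np.pi * config.alpha_freq * t + phi)
        )
    if config.blink_rate:
        eog = np.asarray(model.ch_types) == "eog"
        wave = _blink_waveform(n_samples, fs)
        n_blinks = rng.poisson(config.blink_rate * duration / 60.0)
        leak = np.where(eog, 1.0, config.blink_leakage)
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n_samples - len(wave)))
            seg = wave[: n_samples - start]
            x[:, start : start + len(seg)] += config.blink_amp * np.outer(leak, seg)
    return x


def simulate_experiment(plan: list[StimulusSequence], model: ForwardModel,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> EpochSet:
    """One epoch per planned trial, labels carried through."""
    if len(plan) == 0:
        meta = pd.DataFrame(
            {"condition": [], "orientation": [], "regularity": [],
             "variability": [], "n_targets": []}
        )
        return EpochSet(
            data=np.zeros((0, len(model.ch_names), 0)),
            sfreq=config.sampling_rate,
            ch_names=list(model.ch_names),
            ch_types=list(model.ch_types),
            metadata=meta,
        )
    data = np.stack([simulate_trial(seq, model, config, rng) for seq in plan])
    meta = pd.DataFrame(
        {
            "condition": [s.condition.label for s in plan],
            "orientation": [s.condition.orientation for s in plan],
            "regularity": [s.condition.regularity for s in plan],
            "variability": [s.condition.variability for s in plan],
            "n_targets": [len(s.target_onsets_ms) for s in plan],
        }
    )
    return EpochSet(
        data=data,
        sfreq=config.sampling_rate,
        ch_names=list(model.ch_names),
        ch_types=list(model.ch_types),
        metadata=meta,
    )
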
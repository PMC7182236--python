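"""Narrowband spatial filtering and Fourier phase extraction.

SSVEPs are represented as an optimally weighted sum of all scalp sensors
via rhythmic entrainment source separation (RESS): a generalized
eigendecomposition that maximizes covariance in a narrow band around the
target frequency against covariance at flanking frequencies.  Projected
single-trial series are Tukey-tapered, zero-padded to a common 10 s
length (0.1 Hz resolution), and Fourier-transformed; the phase at the
frequency of interest feeds the phase-clustering statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .epochs import EpochSet

__all__ = [
    "AnalysisWindow",
    "FilterParams",
    "SpatialFilter",
    "ComplexSpectrum",
    "truncate_detrend",
    "narrowband",
    "ress_fit",
    "ress_project",
    "spectrum",
    "phase_at",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """Post-onset analysis window (skips initial evoked transients)."""

    start_offset: float = 0.5  # s after RSVP onset
    length: float = 3.0  # s; 6.5 for the 6 Hz experiments

    def sample_slice(self, sfreq: float, n_samples: int) -> slice:
        start = int(round(self.start_offset * sfreq))
        stop = start + int(round(self.length * sfreq))
        if stop > n_samples:
            raise ValueError(
                f"window [{self.start_offset}, {self.start_offset + self.length}] s "
                f"exceeds epoch of {n_samples / sfreq:g} s"
            )
        return slice(start, stop)


@dataclass(frozen=True)
class FilterParams:
    """RESS bandwidths: signal +/-0.5 Hz, noise at +/-1 Hz flanks."""

    signal_bandwidth: float = 0.5  # Hz half-width -> Gaussian FWHM = 2x
    noise_offset: float = 1.0  # Hz distance of flanking bands
    noise_fwhm: float = 0.5  # Hz FWHM of flanking Gaussians
    shrinkage: float = 0.01  # fraction of mean eigenvalue added to R

    def __post_init__(self):
        if min(self.signal_bandwidth, self.noise_offset, self.noise_fwhm) <= 0:
            raise ValueError("bandwidths must be positive")
        if self.noise_offset <= self.signal_bandwidth:
            raise ValueError("noise bands overlap the signal band")


@dataclass
class SpatialFilter:
    """Channel weights maximizing narrowband SNR at one frequency."""

    weights: np.ndarray
    eigenvalue: float
    target_frequency: float
    condition: str
    topography: np.ndarray
    ch_names: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "channel": self.ch_names,
                "weight": self.weights,
                "topography": self.topography,
            }
        )


@dataclass
class ComplexSpectrum:
    """Per-trial complex Fourier coefficients on a uniform frequency grid."""

    coefficients: np.ndarray  # (trials, freqs)
    frequencies: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("coefficients", data=self.coefficients,
                              compression="gzip")
            fh.create_dataset("frequencies", data=self.frequencies)

    @classmethod
    def load(cls, path) -> "ComplexSpectrum":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(coefficients=fh["coefficients"][()],
                       frequencies=fh["frequencies"][()])


def truncate_detrend(epochs: EpochSet, window: AnalysisWindow) -> EpochSet:
    """Restrict every trial to the analysis window and remove linear trends."""
    sl = window.sample_slice(epochs.sfreq, epochs.n_samples)
    out = epochs.copy()
    out.data = signal.detrend(epochs.data[:, :, sl], axis=2, type="linear")
    return out


def _gaussian_gain(freqs: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((freqs - center) ** 2) / (2.0 * sigma**2))


def narrowband(series: np.ndarray, sfreq: float, center: float,
               fwhm: float) -> np.ndarray:
    """Zero-phase frequency-domain Gaussian filter, unit gain at center."""
    if center >= sfreq / 2:
        raise ValueError(f"center {center} Hz at or above Nyquist")
    n = series.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    gain = _gaussian_gain(freqs, center, fwhm)
    return np.fft.irfft(np.fft.rfft(series, axis=-1) * gain, n=n, axis=-1)


def _mean_trial_cov(data: np.ndarray) -> np.ndarray:
    """Average of per-trial channel covariances; (trials, channels, samples)."""
    centered = data - data.mean(axis=2, keepdims=True)
    n = data.shape[2] - 1
    return np.einsum("tcs,tds->cd", centered, centered) / (n * data.shape[0])


def ress_fit(epochs: EpochSet, f_target: float,
             params: FilterParams = FilterParams(),
             condition: str = "") -> SpatialFilter:
    """Derive the RESS spatial filter for one frequency (scalp channels).

    S is the mean per-trial covariance of data filtered at the target
    (Gaussian, FWHM = 2 x signal bandwidth); R pools the covariances of
    the two flanking bands at +/- ``noise_offset`` Hz (FWHM
    ``noise_fwhm``), then receives a ridge of ``shrinkage`` x mean
    eigenvalue.  The filter is the leading generalized eigenvector of
    (S, R); its sign is fixed so the largest-|weight| entry is positive.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    scalp = epochs.scalp_picks()
    data = epochs.data[:, scalp, :]
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite data")
    fs = epochs.sfreq

    sig = narrowband(data, fs, f_target, 2.0 * params.signal_bandwidth)
    S = _mean_trial_cov(sig)
    R = np.zeros_like(S)
    for off in (-params.noise_offset, +params.noise_offset):
        nb = narrowband(data, fs, f_target + off, params.noise_fwhm)
        R += _mean_trial_cov(nb)
    R /= 2.0
    R_reg = R + params.shrinkage * np.mean(np.linalg.eigvalsh(R)) * np.eye(len(R))

    rank = np.linalg.matrix_rank(S)
    if rank < len(S) - 1:  # one null dimension is expected under average reference
        import warnings

        warnings.warn(
            f"signal covariance rank-deficient ({rank}/{len(S)}); "
            "solution stabilized by the noise-ridge alone"
        )
    evals, evecs = linalg.eigh(S, R_reg)
    w = evecs[:, -1]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    topo = S @ w
    topo = topo / np.linalg.norm(topo)
    return SpatialFilter(
        weights=w,
        eigenvalue=float(evals[-1]),
        target_frequency=f_target,
        condition=condition,
        topography=topo,
        ch_names=[epochs.ch_names[i] for i in scalp],
    )


def ress_project(epochs: EpochSet, filt: SpatialFilter) -> np.ndarray:
    """Weighted channel sum per trial -> (trials, samples) component series."""
    scalp = epochs.scalp_picks()
    names = [epochs.ch_names[i] for i in scalp]
    if names != filt.ch_names:
        raise ValueError("montage mismatch between epochs and filter")
    return np.einsum("c,tcs->ts", filt.weights, epochs.data[:, scalp, :])


def spectrum(trials: np.ndarray, sfreq: float, tukey_alpha: float = 0.25,
             pad_to: float = 10.0) -> ComplexSpectrum:
    """Tukey-tapered, zero-padded DFT of each trial.

    ``pad_to`` seconds sets the frequency-grid spacing to 1/pad_to
    (10 s -> 0.1 Hz, the common resolution across experiments).
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    n = trials.shape[1]
    n_pad = int(round(pad_to * sfreq))
    if n_pad < n:
        raise ValueError(f"pad_to {pad_to} s shorter than data ({n / sfreq:g} s)")
    win = signal.windows.tukey(n, alpha=tukey_alpha)
    coeffs = np.fft.rfft(trials * win, n=n_pad, axis=1)
    freqs = np.fft.rfftfreq(n_pad, 1.0 / sfreq)
    return ComplexSpectrum(coefficients=coeffs, frequencies=freqs)


def phase_at(spec: ComplexSpectrum, f: float, tol: float = 1e-9):
    """Per-trial phase angles at an on-grid frequency (no nearest-bin snap)."""
    from .phase_stats import PhaseSet

    diffs = np.abs(spec.frequencies - f)
    idx = int(np.argmin(diffs))
    if diffs[idx] > tol:
        raise ValueError(
            f"{f} Hz is not on the {spec.resolution:g} Hz grid "
            f"(nearest bin {spec.frequencies[idx]:g} Hz)"
        )
    return PhaseSet(angles=np.angle(spec.coefficients[:, idx]))
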
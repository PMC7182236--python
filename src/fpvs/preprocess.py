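"""Artifact screening cascade for epoched EEG.

The cascade mirrors the classical statistics-threshold approach used with
the FASTER toolbox: all criteria are z-scores of simple summary metrics,
computed across channels or across epochs, with |z| > 3 flagging an
outlier.  The stages, in order:

1. whole-recording channel screen (variance, mean pairwise correlation,
   Hurst exponent) -> bad channels interpolated by spherical splines;
2. epoch-level screen on channel-averaged amplitude range, variance and
   channel deviation -> epoch rejected;
3. within-epoch channel screen (variance, median gradient, amplitude
   range, deviation) -> per-epoch interpolation;
4. condition-wise epoch screen (same metrics plus maximum EOG value),
   z-scored within condition -> epoch rejected;
5. epochs with more than 12 interpolated channels discarded;

followed by a kurtosis screen (single- and all-channel mean kurtosis,
+/- 5 SD) and a spectral-deviation screen against the median log-spectrum
(0-2 Hz window: +/-50 dB, blink energy; 20-40 Hz window: +25/-100 dB,
muscle activity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import signal, stats

from .epochs import EpochSet, montage_positions

__all__ = [
    "ScreeningParams",
    "RejectionReport",
    "rereference",
    "screen_channels",
    "interpolate",
    "screen_epochs",
    "hurst_dfa",
    "spherical_spline_matrix",
]


@dataclass(frozen=True)
class ScreeningParams:
    z_threshold: float = 3.0
    kurtosis_sd: float = 5.0
    max_interpolated_per_epoch: int = 12
    # (f_lo, f_hi, upper_dB, lower_dB) deviation windows vs. baseline
    spectral_windows: tuple = (
        (0.0, 2.0, 50.0, -50.0),
        (20.0, 40.0, 25.0, -100.0),
    )

    def __post_init__(self):
        if self.z_threshold <= 0 or self.kurtosis_sd <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RejectionReport:
    """Which epochs were dropped, why, and what was interpolated."""

    n_input: int
    rejected: dict = field(default_factory=dict)  # epoch id -> [reason, ...]
    interpolated: dict = field(default_factory=dict)  # epoch id -> [channel, ...]
    globally_interpolated: list = field(default_factory=list)
    condition_of: dict = field(default_factory=dict)  # epoch id -> label

    def add(self, epoch_id: int, reason: str) -> None:
        self.rejected.setdefault(int(epoch_id), []).append(reason)

    @property
    def rejected_ids(self) -> list[int]:
        return sorted(self.rejected)

    def percentages(self) -> pd.DataFrame:
        """Per-condition rejection percentages (Table-1-style)."""
        conds = pd.Series(self.condition_of)
        rows = []
        for label, ids in conds.groupby(conds).groups.items():
            n = len(ids)
            n_rej = sum(1 for i in ids if i in self.rejected)
            rows.append((label, n, n_rej, 100.0 * n_rej / n if n else 0.0))
        return pd.DataFrame(rows, columns=["condition", "n", "n_rejected", "pct"])

    def to_json(self, path) -> None:
        payload = {
            "n_input": self.n_input,
            "rejected": {str(k): v for k, v in self.rejected.items()},
            "interpolated": {str(k): v for k, v in self.interpolated.items()},
            "globally_interpolated": self.globally_interpolated,
            "percentages": self.percentages().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# referencing


def rereference(epochs: EpochSet, mode: str = "average") -> EpochSet:
    """Re-reference scalp channels to their average or to a named electrode.

    EOG channels are bipolar and left untouched.
    """
    out = epochs.copy()
    scalp = epochs.scalp_picks()
    if mode == "average":
        ref = out.data[:, scalp, :].mean(axis=1, keepdims=True)
        out.data[:, scalp, :] -= ref
    else:
        idx = epochs.pick_channel(mode)
        out.data[:, scalp, :] -= out.data[:, idx : idx + 1, :]
    return out


# ---------------------------------------------------------------------------
# channel-level screening


def hurst_dfa(x: np.ndarray, min_window: int = 16, max_window: int = 256) -> float:
    """Hurst exponent by detrended fluctuation analysis.

    Dyadic window sizes between ``min_window`` and ``max_window``; the
    exponent is the log-log slope of fluctuation versus window size on
    the cumulative-sum profile.
    """
    x = np.asarray(x, float)
    profile = np.cumsum(x - x.mean())
    scales = [s for s in (16, 32, 64, 128, 256) if min_window <= s <= max_window
              and s <= len(x) // 4]
    if len(scales) < 2:
        raise ValueError("series too short for DFA")
    flucts = []
    for s in scales:
        n_seg = len(profile) // s
        segs = profile[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s)
        # per-segment linear detrend via least squares
        A = np.vstack([t, np.ones(s)]).T
        coef, *_ = np.linalg.lstsq(A, segs.T, rcond=None)
        resid = segs.T - A @ coef
        flucts.append(np.sqrt(np.mean(resid**2)))
    slope = np.polyfit(np.log(scales), np.log(flucts), 1)[0]
    return float(slope)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def screen_channels(epochs: EpochSet, params: ScreeningParams = ScreeningParams()
                    ) -> set[str]:
    """Flag scalp channels whose variance, mean correlation, or Hurst
    exponent is an outlier (|z| > threshold) over the whole recording."""
    scalp = epochs.scalp_picks()
    if len(scalp) < 4:
        raise ValueError("need at least 4 scalp channels")
    # concatenate epochs channel-wise
    x = epochs.data[:, scalp, :].transpose(1, 0, 2).reshape(len(scalp), -1)
    if np.allclose(x.std(axis=1), 0):
        raise ValueError("constant recording: channel metrics undefined")
    variance = x.var(axis=1)
    corr = np.corrcoef(x)
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(np.abs(corr), axis=1)
    hurst = np.array([hurst_dfa(ch) for ch in x])
    bad = np.zeros(len(scalp), dtype=bool)
    for metric in (variance, hurst):
        bad |= np.abs(_zscore(metric)) > params.z_threshold
    # low mean correlation marks a disconnected channel; high correlation is
    # what healthy neighboring electrodes look like, so this one is one-sided
    bad |= _zscore(mean_corr) < -params.z_threshold
    return {epochs.ch_names[scalp[i]] for i in np.flatnonzero(bad)}


# ---------------------------------------------------------------------------
# spherical spline interpolation


def _g_matrix(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Legendre series g(cos) = 1/(4*pi) * sum (2n+1)/(n(n+1))^m P_n(cos)."""
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** stiffness
    return npleg.legval(np.clip(cosang, -1, 1), coeffs) / (4 * np.pi)


def spherical_spline_matrix(pos_from: np.ndarray, pos_to: np.ndarray,
                            stiffness: int = 4, reg: float = 1e-5) -> np.ndarray:
    """Mapping matrix reconstructing ``pos_to`` channels from ``pos_from``.

    Positions are projected onto the unit sphere.  ``stiffness`` is the
    spline order m and ``reg`` the ridge term added to the diagonal of
    the Gram matrix.
    """
    u_from = pos_from / np.linalg.norm(pos_from, axis=1, keepdims=True)
    u_to = pos_to / np.linalg.norm(pos_to, axis=1, keepdims=True)
    G = _g_matrix(u_from @ u_from.T, stiffness)
    G_to = _g_matrix(u_to @ u_from.T, stiffness)
    n = len(u_from)
    # solve [G+reg*I, 1; 1^T, 0] [c; c0] = [data; 0]
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    inv = np.linalg.inv(A)
    # interpolated = G_to @ c + c0; express as linear map on the data
    mapping = np.hstack([G_to, np.ones((len(u_to), 1))]) @ inv[:, :n]
    return mapping


def interpolate(epochs: EpochSet, channels: set[str] | list[str],
                montage: str | None = None) -> EpochSet:
    """Replace the named scalp channels by spherical-spline estimates."""
    channels = sorted(set(channels))
    if not channels:
        return epochs.copy()
    scalp = epochs.scalp_picks()
    bad_idx = np.array([epochs.pick_channel(c) for c in channels])
    good_idx = np.array([i for i in scalp if i not in set(bad_idx)])
    if len(good_idx) < 3 * len(scalp) / 4:
        raise ValueError(
            f"only {len(good_idx)} of {len(scalp)} scalp channels usable; "
            "too few for stable interpolation"
        )
    pos = montage_positions(epochs.ch_names, montage or epochs.montage)
    mapping = spherical_spline_matrix(pos[good_idx], pos[bad_idx])
    out = epochs.copy()
    out.data[:, bad_idx, :] = np.einsum(
        "bg,tgs->tbs", mapping, epochs.data[:, good_idx, :]
    )
    return out


# ---------------------------------------------------------------------------
# epoch-level screening


def _epoch_metrics(data: np.ndarray) -> np.ndarray:
    """Channel-averaged amplitude range, variance, deviation per epoch."""
    rng_ = np.ptp(data, axis=2).mean(axis=1)
    var = data.var(axis=2).mean(axis=1)
    ch_mean = data.mean(axis=2)  # (trials, channels)
    dev = np.abs(ch_mean - ch_mean.mean(axis=1, keepdims=True)).mean(axis=1)
    return np.column_stack([rng_, var, dev])


_EPOCH_REASONS = ("amplitude_range", "variance", "channel_deviation")


def screen_epochs(epochs: EpochSet, params: ScreeningParams = ScreeningParams(),
                  montage: str | None = None) -> tuple[EpochSet, RejectionReport]:
    """Run the epoch-level screening cascade; returns surviving epochs and
    a report with per-epoch reasons and per-condition percentages."""
    if epochs.conditions.value_counts().min() < 2:
        raise ValueError("need at least 2 epochs per condition")
    report = RejectionReport(n_input=epochs.n_trials)
    report.condition_of = dict(enumerate(epochs.conditions))
    scalp = epochs.scalp_picks()
    eog = epochs.eog_picks()
    alive = np.ones(epochs.n_trials, dtype=bool)
    data = epochs.data

    # stage: epoch-level screen on channel-averaged metrics
    metrics = _epoch_metrics(data[:, scalp, :])
    for j, reason in enumerate(_EPOCH_REASONS):
        z = _zscore(metrics[:, j])
        for i in np.flatnonzero(np.abs(z) > params.z_threshold):
            report.add(i, reason)
            alive[i] = False

    # stage: within-epoch channel screen -> per-epoch interpolation
    pos = montage_positions(epochs.ch_names, montage or epochs.montage)
    data = data.copy()
    for i in np.flatnonzero(alive):
        x = data[i][scalp]
        var = x.var(axis=1)
        grad = np.median(np.abs(np.diff(x, axis=1)), axis=1)
        rng_ = np.ptp(x, axis=1)
        dev = np.abs(x.mean(axis=1) - x.mean())
        bad = np.zeros(len(scalp), dtype=bool)
        for metric in (var, grad, rng_, dev):
            bad |= np.abs(_zscore(metric)) > params.z_threshold
        bad_ch = [epochs.ch_names[scalp[k]] for k in np.flatnonzero(bad)]
        if not bad_ch:
            continue
        report.interpolated[i] = bad_ch
        if len(bad_ch) > params.max_interpolated_per_epoch:
            report.add(i, "over_interpolated")
            alive[i] = False
            continue
        bad_idx = scalp[np.flatnonzero(bad)]
        good_idx = np.array([c for c in scalp if c not in set(bad_idx)])
        if len(good_idx) < 3 * len(scalp) / 4:
            report.add(i, "over_interpolated")
            alive[i] = False
            continue
        mapping = spherical_spline_matrix(pos[good_idx], pos[bad_idx])
        data[i][bad_idx] = mapping @ data[i][good_idx]

    # stage: condition-wise epoch screen, including max EOG value
    for label in epochs.conditions.unique():
        idx = np.flatnonzero((epochs.conditions == label).to_numpy() & alive)
        if len(idx) < 2:
            continue
        m = _epoch_metrics(data[idx][:, scalp, :])
        eog_max = (
            np.abs(data[idx][:, eog, :]).max(axis=(1, 2))
            if len(eog)
            else np.zeros(len(idx))
        )
        m = np.column_stack([m, eog_max])
        reasons = _EPOCH_REASONS + ("eog_max",)
        for j, reason in enumerate(reasons):
            z = _zscore(m[:, j])
            for k in np.flatnonzero(np.abs(z) > params.z_threshold):
                report.add(idx[k], reason)
                alive[idx[k]] = False

    # stage: kurtosis screen (single- and all-channel)
    idx = np.flatnonzero(alive)
    if len(idx) >= 2:
        kurt = stats.kurtosis(data[idx][:, scalp, :], axis=2)  # (epochs, channels)
        # single-channel: any channel's kurtosis beyond kurtosis_sd SDs of
        # that channel's mean over epochs
        mu = kurt.mean(axis=0)
        sd = kurt.std(axis=0)
        sd[sd == 0] = np.inf
        single = np.abs(kurt - mu) / sd > params.kurtosis_sd
        # all-channel: epoch-mean kurtosis across channels
        allch = np.abs(_zscore(kurt.mean(axis=1))) > params.kurtosis_sd
        for k in np.flatnonzero(single.any(axis=1) | allch):
            report.add(idx[k], "kurtosis")
            alive[idx[k]] = False

    # stage: spectral deviation screen vs. median baseline
    idx = np.flatnonzero(alive)
    if len(idx) >= 2:
        freqs, psd = signal.periodogram(data[idx][:, scalp, :], epochs.sfreq, axis=2)
        db = 10 * np.log10(psd.mean(axis=1) + 1e-30)  # (epochs, freqs)
        baseline = np.median(db, axis=0)
        devia = db - baseline
        for f_lo, f_hi, upper, lower in params.spectral_windows:
            band = (freqs >= f_lo) & (freqs <= f_hi)
            over = (devia[:, band] > upper).any(axis=1) | (
                devia[:, band] < lower
            ).any(axis=1)
            for k in np.flatnonzero(over):
                if alive[idx[k]]:
                    report.add(idx[k], "spectral_deviation")
                    alive[idx[k]] = False

    out = EpochSet(
        data=data[alive],
        sfreq=epochs.sfreq,
        ch_names=list(epochs.ch_names),
        ch_types=list(epochs.ch_types),
        metadata=epochs.metadata.iloc[alive].reset_index(drop=True),
        montage=epochs.montage,
    )
    empty = set(epochs.conditions.unique()) - set(out.conditions.unique())
    if empty:
        import warnings

        warnings.warn(f"all epochs rejected for condition(s): {sorted(empty)}")
    return out, report
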
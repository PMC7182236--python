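"""Artifact screening: referencing, channel metrics, interpolation, cascade."""

import numpy as np
import pandas as pd
import pytest

from fpvs import design
from fpvs.epochs import EpochSet, default_channel_names, montage_positions
from fpvs.preprocess import (ScreeningParams, hurst_dfa, interpolate,
                             rereference, screen_channels, screen_epochs,
                             spherical_spline_matrix)
from fpvs.simulate import ForwardModel, SimulationConfig, simulate_experiment


def make_epochs(n_trials=12, n_conditions=2, seed=0, sigma=1.0):
    """Plain iid-noise epochs on the full 64+4 montage."""
    rng = np.random.default_rng(seed)
    names, types = default_channel_names()
    data = sigma * rng.standard_normal((n_trials, len(names), 512))
    meta = pd.DataFrame(
        {"condition": [f"c{i % n_conditions}" for i in range(n_trials)]}
    )
    return EpochSet(data=data, sfreq=256.0, ch_names=names, ch_types=types,
                    metadata=meta)


class TestRereference:
    def test_average_zeroes_scalp_mean(self):
        ep = rereference(make_epochs(), "average")
        scalp_mean = ep.data[:, ep.scalp_picks(), :].mean(axis=1)
        assert np.abs(scalp_mean).max() < 1e-10

    def test_channel_mode_zeroes_reference(self):
        ep = rereference(make_epochs(), "Cz")
        cz = ep.pick_channel("Cz")
        assert np.all(ep.data[:, cz, :] == 0)

    def test_average_idempotent(self):
        once = rereference(make_epochs(), "average")
        twice = rereference(once, "average")
        assert np.allclose(once.data, twice.data)

    def test_eog_untouched(self):
        ep = make_epochs()
        out = rereference(ep, "average")
        eog = ep.eog_picks()
        assert np.array_equal(out.data[:, eog, :], ep.data[:, eog, :])

    def test_missing_channel(self):
        with pytest.raises(KeyError):
            rereference(make_epochs(), "Xz")


class TestScreenChannels:
    def test_high_variance_channel_flagged(self):
        ep = make_epochs(seed=1)
        idx = ep.pick_channel("C3")
        ep.data[:, idx, :] *= 10.0
        assert "C3" in screen_channels(ep)

    def test_homogeneous_channels_pass(self):
        # iid channels: with |z| > 3 on 64 channels, false positives are rare
        assert screen_channels(make_epochs(seed=2)) == set()

    def test_duplicated_neighbor_not_flagged_by_correlation(self):
        ep = make_epochs(seed=3)
        a, b = ep.pick_channel("O1"), ep.pick_channel("O2")
        ep.data[:, b, :] = ep.data[:, a, :]
        bad = screen_channels(ep)
        # perfect correlation is high, not low: the pair may trip other
        # metrics only by chance, not the correlation criterion
        assert not {"O1", "O2"} <= bad

    def test_constant_recording_raises(self):
        ep = make_epochs()
        ep.data[:] = 0.0
        with pytest.raises(ValueError, match="constant"):
            screen_channels(ep)


class TestHurst:
    def test_white_noise_near_half(self):
        rng = np.random.default_rng(0)
        vals = [hurst_dfa(rng.standard_normal(4096)) for _ in range(10)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_persistent_series_above_half(self):
        rng = np.random.default_rng(1)
        walk_increments = np.cumsum(rng.standard_normal(4096))  # integrated
        assert hurst_dfa(walk_increments) > 1.0


class TestInterpolation:
    def test_empty_set_is_identity(self):
        ep = make_epochs()
        out = interpolate(ep, set())
        assert np.array_equal(out.data, ep.data)

    def test_smooth_field_reconstruction(self):
        """A channel lying on a smooth scalp field is recovered within a few
        percent RMS from its neighbors."""
        names, types = default_channel_names()
        pos = montage_positions(names)
        rng = np.random.default_rng(4)
        # smooth random field: four broad Gaussian spatial components with
        # random time courses
        comps = np.stack([
            np.exp(-np.sum((pos[:64] - c) ** 2, axis=1) / (2 * 0.07**2))
            for c in pos[[0, 20, 40, 63]]
        ])  # (4, 64)
        courses = rng.standard_normal((5, 4, 512))
        scalp = np.einsum("tks,kn->tns", courses, comps)
        data = np.concatenate([scalp, np.zeros((5, 4, 512))], axis=1)
        ep = EpochSet(data=data, sfreq=256.0, ch_names=names, ch_types=types,
                      metadata=pd.DataFrame({"condition": ["c"] * 5}))
        target = "POz"
        idx = ep.pick_channel(target)
        truth = ep.data[:, idx, :].copy()
        ep.data[:, idx, :] = 0.0
        out = interpolate(ep, {target})
        rms_err = np.sqrt(np.mean((out.data[:, idx, :] - truth) ** 2))
        rms = np.sqrt(np.mean(truth**2))
        assert rms_err / rms < 0.05

    def test_against_mne_oracle(self):
        """Spherical-spline mapping agrees with mne's interpolate_bads."""
        import mne

        ep = make_epochs(n_trials=3, seed=5)
        bads = ["Oz", "C3"]
        ours = interpolate(ep, bads)
        m = ep.to_mne()
        m.info["bads"] = bads
        m.interpolate_bads(verbose="error")
        theirs = m.get_data() * 1e6
        for name in bads:
            i = ep.pick_channel(name)
            a, b = ours.data[:, i, :], theirs[:, i, :]
            denom = np.sqrt(np.mean(b**2))
            assert np.sqrt(np.mean((a - b) ** 2)) / denom < 0.05

    def test_too_many_bads_rejected(self):
        ep = make_epochs()
        bads = set(ep.ch_names[:20])
        with pytest.raises(ValueError, match="too few"):
            interpolate(ep, bads)

    def test_mapping_preserves_constants(self):
        names, _ = default_channel_names()
        pos = montage_positions(names)
        mapping = spherical_spline_matrix(pos[:60], pos[60:64])
        assert np.allclose(mapping.sum(axis=1), 1.0, atol=1e-6)


class TestScreenEpochs:
    def test_clean_small_set_no_rejections(self):
        ep = make_epochs(n_trials=16, seed=6)
        out, report = screen_epochs(ep)
        assert report.rejected == {}
        assert out.n_trials == 16

    def test_eog_blink_rejected(self):
        ep = make_epochs(n_trials=40, seed=7)
        eog = ep.eog_picks()
        ep.data[5, eog, 100:200] += 300.0  # blink-sized EOG transient
        out, report = screen_epochs(ep)
        assert 5 in report.rejected
        assert "eog_max" in report.rejected[5]

    def test_over_interpolated_epoch_discarded(self):
        ep = make_epochs(n_trials=40, seed=8)
        scalp = ep.scalp_picks()
        ep.data[3, scalp[:13], :] *= 40.0  # 13 corrupted channels
        out, report = screen_epochs(ep)
        assert 3 in report.rejected
        reasons = report.rejected[3]
        assert "over_interpolated" in reasons or "amplitude_range" in reasons

    def test_counts_partition(self):
        ep = make_epochs(n_trials=30, seed=9)
        ep.data[2] *= 8.0
        out, report = screen_epochs(ep)
        assert out.n_trials + len(report.rejected) == ep.n_trials

    def test_permutation_equivariance(self):
        ep = make_epochs(n_trials=24, seed=10)
        ep.data[4] *= 6.0
        _, r1 = screen_epochs(ep)
        perm = np.random.default_rng(0).permutation(ep.n_trials)
        ep2 = ep.select_trials(perm)
        _, r2 = screen_epochs(ep2)
        orig_of = {new: old for new, old in enumerate(perm)}
        remapped = {orig_of[i] for i in r2.rejected}
        assert remapped == set(r1.rejected)

    def test_report_percentages_and_json(self, tmp_path):
        ep = make_epochs(n_trials=30, seed=11)
        ep.data[0] *= 8.0
        _, report = screen_epochs(ep)
        pct = report.percentages()
        assert (pct["pct"] >= 0).all() and (pct["pct"] <= 100).all()
        report.to_json(tmp_path / "report.json")
        import json

        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["n_input"] == 30

    def test_too_few_epochs_per_condition(self):
        ep = make_epochs(n_trials=2, n_conditions=2)
        with pytest.raises(ValueError, match="at least 2"):
            screen_epochs(ep)


def test_false_positive_budget(small_forward_model):
    """Rejection percentages on artifact-free simulations stay within a
    small false-positive budget per condition."""
    spec = design.scaled(design.preset("pilot1"), 30)
    import dataclasses

    from fpvs.simulate import ForwardModel

    spec = dataclasses.replace(spec, target_policy=None)
    cfg = SimulationConfig.for_spec(spec)
    fwd = ForwardModel.default()
    rates = []
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        plan = design.build_session_plan(spec, rng)
        ep = simulate_experiment(plan, fwd, cfg, rng)
        ep = rereference(ep, "average")
        _, report = screen_epochs(ep)
        rates.append(report.percentages()["pct"].mean())
    assert np.mean(rates) <= 5.0
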
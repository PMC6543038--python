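"""rsfMRI temporal preprocessing, connectivity, and the edge-wise screens."""

import numpy as np
import pandas as pd
import pytest

from scentstress.connectome import (
    RoiRun,
    bandpass,
    batch_adjusted_effect,
    censor_volumes,
    compute_fd,
    edge_index,
    edgewise_behavior_screen,
    group_edge_difference,
    nuisance_regress,
    preprocess_run,
    rsfc_matrix,
    seed_profile,
)


def make_run(data, tr=1.0, motion=None, nuisance=None, sid="s"):
    data = np.asarray(data, dtype=float)
    t = data.shape[0]
    if motion is None:
        motion = np.zeros((t, 6))
    if nuisance is None:
        nuisance = np.zeros((t, 0))
    return RoiRun(subject_id=sid, run_id=f"{sid}_r1", tr=tr, data=data, motion=motion, nuisance=nuisance)


def random_z_mats(rng, n, r):
    mats = []
    for _ in range(n):
        z = rng.normal(0, 0.2, (r, r))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        mats.append(z)
    return mats


class TestComputeFd:
    def test_zero_motion_all_zero(self):
        assert compute_fd(np.zeros((100, 6))) == pytest.approx(np.zeros(100))

    def test_single_translation_step(self):
        motion = np.zeros((5, 6))
        motion[2:, 0] = 0.1
        fd = compute_fd(motion)
        assert fd == pytest.approx([0, 0, 0.1, 0, 0])

    def test_rotation_converted_at_radius(self):
        motion = np.zeros((4, 6))
        motion[1:, 3] = 0.01  # rad
        fd = compute_fd(motion, radius_mm=5.0)
        assert fd[1] == pytest.approx(0.05)

    def test_wrong_columns_raise(self):
        with pytest.raises(ValueError, match="6 columns"):
            compute_fd(np.zeros((10, 5)))


class TestCensorVolumes:
    def test_motion_free_2400_volume_run_keeps_2390(self):
        keep, excluded, frac = censor_volumes(np.zeros(2400))
        assert keep.sum() == 2390
        assert not excluded and frac == 0

    def test_flag_and_neighbor_removal_toy_case(self):
        keep, excluded, frac = censor_volumes(np.array([0, 0, 0.25, 0, 0]), drop_first=0)
        assert list(np.flatnonzero(keep)) == [0, 4]
        assert excluded  # 3/5 of the volumes were motion-removed

    def test_quarter_removed_run_is_excluded(self):
        fd = np.zeros(100)
        fd[np.arange(2, 100, 8)] = 0.5  # each flag removes ~3 volumes
        keep, excluded, frac = censor_volumes(fd, drop_first=0)
        assert 100 - keep.sum() >= 25
        assert excluded and frac > 0.2


class TestBandpass:
    @pytest.mark.parametrize("freq, bound, keep", [(0.05, 0.9, True), (0.3, 0.1, False), (0.005, 0.1, False)])
    def test_amplitude_contract(self, freq, bound, keep):
        t = np.arange(2400.0)
        y = bandpass(np.sin(2 * np.pi * freq * t)[:, None], tr=1.0)
        amp = np.sqrt(2) * y[200:-200].std()
        assert (amp >= bound) if keep else (amp <= bound)

    def test_dc_removed(self):
        y = bandpass(np.full((2400, 2), 7.0), tr=1.0)
        assert np.abs(y).max() < 1e-9

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros((100, 1)), tr=1.0, low=0.01, high=0.6)


class TestNuisanceRegress:
    def test_residuals_orthogonal_to_regressors(self, rng):
        data = rng.normal(0, 1, (200, 5))
        reg = rng.normal(0, 1, (200, 3))
        res = nuisance_regress(data, reg)
        assert np.abs(res.T @ reg).max() < 1e-8
        assert np.abs(res.sum(axis=0)).max() < 1e-8  # intercept included

    def test_region_equal_to_regressor_vanishes(self, rng):
        reg = rng.normal(0, 1, (100, 2))
        res = nuisance_regress(reg[:, :1], reg)
        assert np.abs(res).max() < 1e-10

    def test_signal_recovered_from_known_mixture(self, rng):
        signal = rng.normal(0, 1, 500)
        nuis = rng.normal(0, 1, (500, 2))
        data = (signal + nuis @ np.array([2.0, -1.5]))[:, None]
        res = nuisance_regress(data, nuis)
        corr = np.corrcoef(res[:, 0], signal)[0, 1]
        assert corr >= 0.99

    def test_rank_deficient_design_names_columns(self, rng):
        a = rng.normal(0, 1, 100)
        with pytest.raises(ValueError, match="redundant"):
            nuisance_regress(rng.normal(0, 1, (100, 2)), np.column_stack([a, 2 * a]))


class TestRsfcMatrix:
    def test_duplicated_region_gives_unit_correlation(self, rng):
        x = rng.normal(0, 1, 200)
        m = rsfc_matrix(make_run(np.column_stack([x, x, rng.normal(0, 1, 200)])))
        assert m.r[0, 1] == pytest.approx(1.0)
        assert np.isfinite(m.z[0, 1])  # clipped before atanh

    def test_symmetry_unit_diagonal_and_null_mean(self, rng):
        data = rng.normal(0, 1, (2400, 10))
        m = rsfc_matrix(make_run(data))
        assert m.r == pytest.approx(m.r.T)
        assert np.diag(m.r) == pytest.approx(np.ones(10))
        iu = np.triu_indices(10, 1)
        assert np.abs(m.r[iu]).max() < 0.1
        assert abs(m.r[iu].mean()) < 0.02

    def test_zero_variance_region_raises(self, rng):
        data = rng.normal(0, 1, (100, 3))
        data[:, 1] = 4.2
        with pytest.raises(ValueError, match="zero-variance"):
            rsfc_matrix(make_run(data))

    def test_excluded_run_rejected(self, rng):
        run = make_run(rng.normal(0, 1, (100, 3)))
        run = type(run)(**{**run.__dict__, "excluded": True, "exclusion_reason": "motion"})
        with pytest.raises(ValueError, match="excluded"):
            rsfc_matrix(run)


class TestPreprocessRun:
    def test_spike_free_run_keeps_post_trim_volumes(self, rng):
        run = make_run(rng.normal(0, 1, (400, 5)))
        clean = preprocess_run(run)
        assert clean.data.shape == (390, 5)
        assert not clean.excluded

    def test_spiky_run_is_excluded(self, rng):
        motion = np.zeros((400, 6))
        motion[np.arange(12, 390, 4), 0] += 0.5  # dense spikes
        run = make_run(rng.normal(0, 1, (400, 5)), motion=motion)
        clean = preprocess_run(run)
        assert clean.excluded
        assert "removed" in clean.exclusion_reason

    def test_nuisance_contamination_removed(self, rng):
        # a shared in-band nuisance signal must vanish from the residuals
        t = np.arange(600.0)
        nuis = np.sin(2 * np.pi * 0.04 * t)[:, None]
        data = rng.normal(0, 1, (600, 4)) + nuis @ np.full((1, 4), 3.0)
        clean = preprocess_run(make_run(data, nuisance=nuis))
        filtered_nuis = bandpass(nuis, 1.0)[10:]
        corrs = [abs(np.corrcoef(clean.data[:, j], filtered_nuis[:, 0])[0, 1]) for j in range(4)]
        assert max(corrs) < 0.05


class TestEdgewiseBehaviorScreen:
    def test_67_regions_yield_2211_edges(self, rng):
        mats = random_z_mats(rng, 6, 67)
        tab = edgewise_behavior_screen(mats, rng.normal(0, 1, 6))
        assert len(tab) == 2211
        iu, ju = edge_index(67)
        assert iu.size == 2211 and np.all(tab.region_i < tab.region_j)

    def test_invariant_to_affine_behavior_rescaling(self, rng):
        mats = random_z_mats(rng, 10, 8)
        y = rng.normal(50, 20, 10)
        t1 = edgewise_behavior_screen(mats, y)
        t2 = edgewise_behavior_screen(mats, 3.5 * y - 100)
        assert t1.r.to_numpy() == pytest.approx(t2.r.to_numpy())
        assert t1.p.to_numpy() == pytest.approx(t2.p.to_numpy())

    def test_q_dominates_p_and_flags_match_alpha(self, rng):
        mats = random_z_mats(rng, 12, 10)
        tab = edgewise_behavior_screen(mats, rng.normal(0, 1, 12), alpha=0.2)
        assert np.all(tab.q >= tab.p - 1e-12)
        assert np.array_equal(tab.significant, tab.q <= 0.2)

    def test_constant_behavior_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edgewise_behavior_screen(random_z_mats(rng, 5, 6), np.ones(5))

    def test_subject_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="per subject"):
            edgewise_behavior_screen(random_z_mats(rng, 5, 6), np.arange(4))


class TestGroupEdgeDifference:
    def test_planted_group_shift_dominates(self, rng):
        r = 10
        iu = np.triu_indices(r, 1)
        planted = [(0, 1), (2, 3), (4, 5)]
        mats = []
        labels = ["low"] * 21 + ["high"] * 21
        for lab in labels:
            z = rng.normal(0, 0.2, (r, r))
            z = (z + z.T) / 2
            for i, j in planted:
                if lab == "high":
                    z[i, j] += 0.5
                    z[j, i] += 0.5
            mats.append(z)
        tab = group_edge_difference(mats, labels, alpha=0.05)
        sig = tab[tab.significant]
        assert {(i, j) for i, j in zip(sig.region_i, sig.region_j)} >= set(planted)
        assert len(sig) <= len(planted) + 2
        # direction: high > low at planted edges (sign = first-minus-second level)
        planted_rows = tab.set_index(["region_i", "region_j"]).loc[planted]
        assert (planted_rows.sign == 1).all()

    def test_label_permutation_null_rarely_rejects(self, rng):
        mats = random_z_mats(rng, 16, 8)
        total = 0
        for _ in range(20):
            labels = rng.permutation(["a"] * 8 + ["b"] * 8)
            total += group_edge_difference(mats, labels, alpha=0.01).significant.sum()
        assert total / 20 < 0.5

    def test_needs_two_groups(self, rng):
        with pytest.raises(ValueError, match="two groups"):
            group_edge_difference(random_z_mats(rng, 5, 6), ["a"] * 5)


class TestBatchAdjustedEffect:
    def test_single_batch_reduces_to_mean_difference(self, rng):
        z = rng.normal(0, 1, 20)
        group = np.repeat(["low", "high"], 10)
        eff = batch_adjusted_effect(z, group, ["b0"] * 20)
        expected = z[:10].mean() - z[10:].mean()  # first sorted level is 'high'
        assert eff.estimate == pytest.approx(z[group == "high"].mean() - z[group == "low"].mean())
        assert eff.model == "ols"

    def test_batch_confounded_null_gives_no_group_effect(self, rng):
        # batch shifts only; groups balanced within batch
        batch = np.repeat(["b0", "b1", "b2"], 12)
        shift = {"b0": -1.0, "b1": 0.0, "b2": 1.5}
        group = np.tile(np.repeat(["g1", "g2"], 6), 3)
        z = np.array([shift[b] for b in batch]) + rng.normal(0, 0.1, 36)
        eff = batch_adjusted_effect(z, group, batch)
        assert abs(eff.estimate) < 0.15
        assert eff.p > 0.05

    def test_planted_effect_recovered_within_ci(self, rng):
        batch = np.repeat([f"b{i}" for i in range(4)], 12)
        group = np.tile(np.repeat(["g1", "g2"], 6), 4)
        z = rng.normal(0, 0.2, 48) + rng.normal(0, 0.3, 4).repeat(12)
        z[group == "g1"] += 0.4
        eff = batch_adjusted_effect(z, group, batch)
        assert eff.estimate == pytest.approx(0.4, abs=2.5 * eff.se + 1e-9)
        assert eff.n_batches == 4


class TestSeedProfile:
    def test_profile_matches_matrix_rows(self, rng):
        mats = random_z_mats(rng, 8, 6)
        prof = seed_profile(mats, seed_region=2)
        stacked = np.asarray(mats)
        expected = np.delete(stacked[:, 2, :].mean(axis=0), 2)
        assert prof.mean_z.to_numpy() == pytest.approx(expected)
        assert len(prof) == 5 and 2 not in set(prof.region)

    def test_planted_seed_block_recovered(self, rng):
        mats = []
        for _ in range(12):
            z = rng.normal(0, 0.1, (8, 8))
            z = (z + z.T) / 2
            z[0, [1, 2, 3]] += 1.0
            z[[1, 2, 3], 0] += 1.0
            mats.append(z)
        prof = seed_profile(mats, seed_region=0, alpha=0.05).set_index("region")
        assert prof.loc[[1, 2, 3], "significant"].all()

    def test_invalid_seed_raises(self, rng):
        with pytest.raises(ValueError, match="parcellation"):
            seed_profile(random_z_mats(rng, 4, 5), seed_region=9)
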
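"""Synthetic cohort generator: oracle structure, determinism, realism knobs."""

import numpy as np
import pytest

import iscmix as im
from iscmix.synthetic import SyntheticCohortConfig, expected_isc, simulate_cohort


def tiny_config(**kw):
    base = dict(
        n_per_group={"child4": 4, "child6": 4, "adult": 4},
        mesh_spec=(2, 2, 3.0),
        seed=5,
    )
    base.update(kw)
    return SyntheticCohortConfig(**base)


class TestExpectedISC:
    def test_zero_coupling_gives_zero(self, small_cohort):
        truth = small_cohort.truth
        t2 = im.CohortTruth(
            coupling=np.zeros_like(truth.coupling),
            subject_ids=truth.subject_ids, groups=truth.groups,
            ages_months=truth.ages_months, effect_nodes=truth.effect_nodes,
            age_slope=0.0, seed=0,
        )
        assert expected_isc(t2, 0, 1, 0) == 0.0

    def test_product_form(self, small_cohort):
        truth = small_cohort.truth
        c = truth.coupling
        assert expected_isc(truth, 2, 3, 1) == pytest.approx(c[2, 1] * c[3, 1])

    def test_near_unit_couplings_approach_one(self):
        delta = 1e-9
        t = im.CohortTruth(
            coupling=np.full((2, 1), 1.0 - delta),
            subject_ids=("a", "b"), groups=("adult", "adult"),
            ages_months=np.array([250.0, 251.0]),
            effect_nodes=np.array([0]), age_slope=0.0, seed=0,
        )
        assert expected_isc(t, 0, 1, 0) == pytest.approx(1.0, abs=1e-8)

    def test_lookup_errors(self, small_cohort):
        with pytest.raises(KeyError):
            expected_isc(small_cohort.truth, "missing", 0, 0)
        with pytest.raises(KeyError):
            expected_isc(small_cohort.truth, 0, 1, 10_000)


class TestSimulateCohort:
    def test_identical_seeds_bitwise_identical(self):
        c1 = simulate_cohort(tiny_config())
        c2 = simulate_cohort(tiny_config())
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.data, s2.data)
        for m1, m2 in zip(c1.motion, c2.motion):
            assert np.array_equal(m1.translations, m2.translations)
        assert np.array_equal(c1.truth.coupling, c2.truth.coupling)

    def test_different_seeds_differ(self):
        c1 = simulate_cohort(tiny_config(seed=5))
        c2 = simulate_cohort(tiny_config(seed=6))
        assert not np.array_equal(c1.subjects[0].data, c2.subjects[0].data)

    def test_unit_variance_components(self, small_cohort):
        # fluctuation around the raw mean should have variance ~1 in
        # amplitude units at 176 volumes
        cfg = small_cohort.config
        core = (small_cohort.subjects[0].data - cfg.raw_mean) / cfg.raw_amplitude
        v = core.var(axis=1)
        assert np.all(np.abs(v - 1.0) < 0.1)

    def test_zero_coupling_gives_near_zero_isc(self):
        cfg = tiny_config(
            coupling={"child4": 0.0, "child6": 0.0, "adult": 0.0},
            baseline_coupling=0.0, age_slope=0.0,
        )
        coh = simulate_cohort(cfg)
        m = im.pairwise_isc(coh.subjects)
        iu = np.triu_indices(12, k=1)
        vals = m.z[:, iu[0], iu[1]]
        # mean off-diagonal ISC ~ 0 within sampling error (SE ~ 1/sqrt(T*npairs))
        assert abs(np.nanmean(vals)) < 3.0 / np.sqrt(176 * iu[0].size)

    def test_adult_coupling_unbiased_over_seeds(self):
        # 20 adults at c = 0.6: mean pairwise r should be ~0.36, |bias| < 3 SE
        means = []
        for seed in range(50):
            cfg = SyntheticCohortConfig(
                n_per_group={"adult": 20},
                mesh_spec=(2, 2, 3.0),
                coupling={"adult": 0.6},
                baseline_coupling=0.6,
                seed=1000 + seed,
            )
            coh = simulate_cohort(cfg)
            m = im.pairwise_isc(coh.subjects)
            iu = np.triu_indices(20, k=1)
            means.append(np.tanh(m.z[:, iu[0], iu[1]]).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.36) < 3 * se

    def test_empirical_correlation_converges_to_oracle(self):
        # smooth signals leave ~T/2.3 effective samples, so individual pairs
        # keep sampling error ~0.03 even at 2000 volumes; the pair-averaged
        # deviation per node must be well inside 0.02
        cfg = tiny_config(n_volumes=2000, n_per_group={"adult": 4, "child4": 4})
        coh = simulate_cohort(cfg)
        m = im.pairwise_isc(coh.subjects)
        n = len(coh.subjects)
        for v in range(coh.mesh.n_nodes):
            devs = []
            for i in range(n):
                for j in range(i + 1, n):
                    r = np.tanh(m.z[v, i, j])
                    dev = r - expected_isc(coh.truth, i, j, v)
                    assert abs(dev) < 0.12  # per-pair sanity bound
                    devs.append(dev)
            assert abs(np.mean(devs)) < 0.02

    def test_age_slope_detectable_across_seeds(self):
        # positive age slope in effect nodes: age correlates positively with
        # mean child-to-adult correlation in >= 95% of seeds at 46 children
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = SyntheticCohortConfig(
                n_per_group={"child4": 23, "child6": 23, "adult": 21},
                mesh_spec=(2, 2, 3.0),
                seed=3000 + seed,
            )
            coh = simulate_cohort(cfg)
            node = int(coh.truth.effect_nodes[0])
            data = np.stack([s.data[node] for s in coh.subjects])
            data = data - data.mean(axis=1, keepdims=True)
            data = data / np.linalg.norm(data, axis=1, keepdims=True)
            R = data @ data.T
            children = [k for k, g in enumerate(coh.truth.groups) if g != "adult"]
            adults = [k for k, g in enumerate(coh.truth.groups) if g == "adult"]
            maturity = R[np.ix_(children, adults)].mean(axis=1)
            ages = coh.truth.ages_months[children]
            if np.corrcoef(ages, maturity)[0, 1] > 0:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_motion_spike_rate_matches_configuration(self):
        cfg = tiny_config(motion_spike_rate=0.08, n_volumes=176)
        coh = simulate_cohort(cfg)
        fracs = []
        for mt in coh.motion:
            fd = im.compute_fd(mt)
            fracs.append((fd > 0.5).mean())
        # each transient spike yields ~2 high-FD volumes
        assert np.mean(fracs) == pytest.approx(0.08, abs=0.04)

    def test_spike_signal_coupling_flag(self):
        cfg = tiny_config(couple_spikes_to_signal=True, motion_spike_rate=0.1)
        coh = simulate_cohort(cfg)
        spiked = False
        for ts, mt in zip(coh.subjects, coh.motion):
            fd = im.compute_fd(mt)
            bad = fd > 0.5
            if bad.any():
                core = (ts.data - cfg.raw_mean) / cfg.raw_amplitude
                if core[:, bad].mean() > 2.0:
                    spiked = True
        assert spiked

    def test_child_ages_fall_in_two_bands(self, small_cohort):
        truth = small_cohort.truth
        a4 = [truth.ages_months[k] for k, g in enumerate(truth.groups) if g == "child4"]
        a6 = [truth.ages_months[k] for k, g in enumerate(truth.groups) if g == "child6"]
        assert np.mean(a4) < 65 < np.mean(a6)


class TestConfigValidation:
    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            simulate_cohort(tiny_config(coupling={"child4": 1.1, "child6": 0.4,
                                                  "adult": 0.4}))

    def test_age_contribution_must_stay_in_range(self):
        with pytest.raises(ValueError, match="coupling"):
            tiny_config(
                coupling={"child4": 0.95, "child6": 0.4, "adult": 0.4},
                age_slope=0.02,
            ).validate()

    def test_ar1_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="ar1"):
            tiny_config(noise_ar1=1.0).validate()

    def test_json_roundtrip(self, tmp_path):
        cfg = tiny_config(age_slope=0.004, effect_nodes=(0, 1))
        cfg.to_json(tmp_path / "cfg.json")
        back = SyntheticCohortConfig.from_json(tmp_path / "cfg.json")
        assert back == cfg


class TestWriteCohort:
    def test_files_written_and_reload_consistent(self, tmp_path):
        coh = simulate_cohort(tiny_config())
        im.write_cohort(coh, tmp_path)
        import pandas as pd

        meta = pd.read_csv(tmp_path / "participants.csv")
        assert len(meta) == len(coh.subjects)
        sid = coh.subjects[0].subject_id
        data = np.loadtxt(tmp_path / f"{sid}_bold.tsv")
        assert np.allclose(data, coh.subjects[0].data, rtol=1e-6)
        from iscmix.motion import read_motion_1d

        mt = read_motion_1d(tmp_path / f"{sid}_motion.1D")
        assert np.allclose(mt.translations, coh.motion[0].translations, atol=1e-5)
        assert np.allclose(
            np.deg2rad(mt.rotations), coh.motion[0].rotations, atol=1e-7
        )
        cfg = SyntheticCohortConfig.from_json(tmp_path / "config.json")
        assert cfg.seed == coh.config.seed
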
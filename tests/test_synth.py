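"""Generator checks: phantom geometry, signal-model correlations,
forward-model consistency and the planted covariate chain."""

import numpy as np
import pytest
from scipy import stats as sps

from pnvf import synth
from pnvf.asl import AslParams, forward_fractional_change
from pnvf.preproc import framewise_displacement


class TestPhantomAnatomy:
    def test_networks_disjoint_and_in_gray(self):
        anat = synth.make_phantom_anatomy((16, 16, 12), n_networks=3, seed=1,
                                          network_radius_vox=2.5,
                                          min_separation_vox=6.0)
        assert anat.n_networks == 3
        for k in range(1, 4):
            net = anat.network_mask(k)
            assert net.any()
            assert (anat.gray[net] > 0.66).all()
        # disjoint by construction of the integer label volume
        assert (anat.networks >= 0).all()
        total = anat.gray + anat.white + anat.csf
        assert total.max() <= 1.0 + 1e-9

    def test_deterministic_given_seed(self):
        a = synth.make_phantom_anatomy((16, 16, 12), 2, seed=7)
        b = synth.make_phantom_anatomy((16, 16, 12), 2, seed=7)
        for name in ("gray", "white", "csf", "networks", "excluded"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    @pytest.mark.parametrize(
        "dims,n_networks",
        [((16, 16, 12), 0), ((4, 4, 4), 1), ((8, 8, 8), 40)],
    )
    def test_invalid_requests_rejected(self, dims, n_networks):
        with pytest.raises(synth.SyntheticError):
            synth.make_phantom_anatomy(dims, n_networks, seed=1)


class TestBoldRun:
    def test_within_network_correlation_matches_target(self, small_anatomy):
        """With zero thermal noise, no spikes and no CO2 gain, the mean
        empirical pairwise correlation between same-network voxels lands
        on the generator's target."""
        spec = synth.CohortSpec(
            dims=small_anatomy.dims, bold_noise_sd=0.0, co2_gain_mean=0.0,
            co2_gain_coupling=0.0, spike_frames=(), spike_mag_mm=(),
        )
        target = 0.6
        rs = []
        for s in range(6):
            run, _ = synth.simulate_bold_run(
                small_anatomy, spec, subject=s, run_index=1, seed=s,
                network_r=[target] * 3,
            )
            net = small_anatomy.network_mask(1)
            ts = run.data[net]
            cm = np.corrcoef(ts)
            iu = np.triu_indices_from(cm, k=1)
            rs.append(cm[iu].mean())
        assert abs(np.mean(rs) - target) < 0.05

    def test_null_generator_groups_indistinguishable(self, small_anatomy):
        """All effects zero: summary statistics of CHD-labeled and
        control-labeled runs come from the same distribution."""
        spec = synth.CohortSpec(
            dims=small_anatomy.dims, group_dr=(0, 0, 0),
            mediator_coupling=(0, 0, 0), cbf_mediator_coupling=(0, 0, 0),
            spike_frames=(), spike_mag_mm=(),
        )
        net = small_anatomy.network_mask(1)
        stats = {0: [], 1: []}
        for g in (0, 1):
            for i in range(25):
                run, _ = synth.simulate_bold_run(
                    small_anatomy, spec, subject=1000 * g + i, run_index=1,
                    seed=1000 * g + i,
                )
                ts = run.data[net]
                cm = np.corrcoef(ts)
                stats[g].append(cm[np.triu_indices_from(cm, k=1)].mean())
        _, p = sps.ttest_ind(stats[0], stats[1])
        assert p > 0.01

    def test_motion_spike_raises_fd_above_threshold(self, small_anatomy):
        spec = synth.CohortSpec(dims=small_anatomy.dims,
                                spike_frames=(70,), spike_mag_mm=(0.5,))
        _, trace = synth.simulate_bold_run(small_anatomy, spec, 0, 1, seed=3)
        fd = framewise_displacement(trace)
        assert fd[70] > 0.2

    def test_bit_reproducible(self, small_anatomy, spec):
        spec = synth.CohortSpec(dims=small_anatomy.dims)
        r1, t1 = synth.simulate_bold_run(small_anatomy, spec, 0, 1, seed=9)
        r2, t2 = synth.simulate_bold_run(small_anatomy, spec, 0, 1, seed=9)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(t1.translations, t2.translations)


class TestAslSeries:
    def test_noiseless_fractional_change_equals_forward_model(self, small_anatomy):
        cbf = np.full(small_anatomy.dims, 60.0)
        acq = synth.simulate_asl_series(small_anatomy, cbf, AslParams(),
                                        seed=1, n_pairs=3, noise_sd=0.0)
        control = acq.data[..., ~acq.is_label].mean(axis=-1)
        label = acq.data[..., acq.is_label].mean(axis=-1)
        slices = np.broadcast_to(
            np.arange(small_anatomy.dims[2])[None, None, :], small_anatomy.dims
        )
        expected = forward_fractional_change(cbf, acq.params, slices)
        frac = (control - label) / control
        assert np.allclose(frac, expected, atol=1e-12)

    def test_zero_flow_means_no_label_contrast(self, small_anatomy):
        cbf = np.zeros(small_anatomy.dims)
        acq = synth.simulate_asl_series(small_anatomy, cbf, AslParams(),
                                        seed=1, n_pairs=2, noise_sd=0.0)
        assert np.array_equal(acq.data[..., 0], acq.data[..., 1])

    def test_45_pairs_give_90_interleaved_volumes(self, small_anatomy):
        cbf = np.full(small_anatomy.dims, 50.0)
        acq = synth.simulate_asl_series(small_anatomy, cbf, AslParams(),
                                        seed=1, n_pairs=45, noise_sd=1.0)
        assert acq.n_volumes == 90
        assert acq.n_pairs == 45
        assert not acq.is_label[0] and acq.is_label[1]
        assert np.array_equal(acq.is_label[::2], np.zeros(45, dtype=bool))


class TestCohort:
    def test_table_counts_match_group_sizes(self):
        spec = synth.CohortSpec(n_chd=24, n_control=64)
        cohort = synth.simulate_cohort(spec, with_imaging=False)
        assert len(cohort.table) == 88
        assert int(cohort.table["group"].sum()) == 24
        assert cohort.table["age"].between(6, 25).all()
        assert set(cohort.table.columns) >= {
            "group", "age", "gender", "nno", "cognition", "age_at_nno",
            "repeat_scan",
        }
        assert int(cohort.table["repeat_scan"].sum()) == 3

    def test_null_a_path_decouples_mediator_from_group(self):
        rs = []
        for seed in range(8):
            spec = synth.CohortSpec(n_chd=40, n_control=40, med_a=0.0,
                                    master_seed=seed)
            t = synth.simulate_cohort(spec, with_imaging=False).table
            rs.append(np.corrcoef(t["group"], t["mediator_std"])[0, 1])
        assert abs(np.mean(rs)) < 2.0 / np.sqrt(8 * 80)

    def test_planted_indirect_effect_recovered_by_ols(self):
        spec = synth.CohortSpec(n_chd=250, n_control=250, med_a=1.0,
                                med_b=1.0, med_c_direct=0.0,
                                med_resid_sd=0.05, out_resid_sd=0.05,
                                master_seed=5)
        t = synth.simulate_cohort(spec, with_imaging=False).table
        g = t["group"].to_numpy(float)
        m = t["mediator_std"].to_numpy(float)
        y = t["outcome_std"].to_numpy(float)
        X1 = np.column_stack([np.ones_like(g), g])
        a = np.linalg.lstsq(X1, m, rcond=None)[0][1]
        X2 = np.column_stack([np.ones_like(g), m, g])
        b = np.linalg.lstsq(X2, y, rcond=None)[0][1]
        assert abs(a * b - 1.0) < 0.05

    def test_cohort_bit_reproducible(self):
        spec = synth.CohortSpec(n_chd=2, n_control=2, dims=(16, 16, 12),
                                network_radius_vox=2.5, min_separation_vox=6.0,
                                master_seed=11)
        c1 = synth.simulate_cohort(spec)
        c2 = synth.simulate_cohort(spec)
        assert c1.table.equals(c2.table)
        assert np.array_equal(c1.subjects[0].runs[0][0].data,
                              c2.subjects[0].runs[0][0].data)
        assert np.array_equal(c1.subjects[-1].asl.data, c2.subjects[-1].asl.data)
        assert np.array_equal(c1.truth.network_r, c2.truth.network_r)
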
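"""Generators: determinism, planted ground truth, parameter validation."""

import numpy as np
import pytest

from sas6flex import DimerModelParams
from sas6flex.synthetic import (
    AdhesionSpec,
    TitrationDesign,
    ToyDimerSpec,
    gen_intensity_series,
    gen_loop_trajectory,
    gen_noe_profile,
    gen_pull_trace,
    gen_shift_profile,
    gen_titration,
)


class TestDeterminism:
    def test_every_generator_is_pure_in_its_seed(self, wt_params):
        design = TitrationDesign.log_spaced(seed=11)
        a = gen_titration(wt_params, design)
        b = gen_titration(wt_params, design)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.polarisation_mP, s2.polarisation_mP)

        n1 = gen_noe_profile(80, (30, 50), seed=5)
        n2 = gen_noe_profile(80, (30, 50), seed=5)
        assert np.array_equal(n1.noe, n2.noe)

        t1 = gen_loop_trajectory(ToyDimerSpec(seed=5), 30)
        t2 = gen_loop_trajectory(ToyDimerSpec(seed=5), 30)
        assert np.array_equal(t1.coords, t2.coords)

        p1 = gen_pull_trace(AdhesionSpec(seed=5, n_steps=200))
        p2 = gen_pull_trace(AdhesionSpec(seed=5, n_steps=200))
        assert np.array_equal(p1.cv_A, p2.cv_A)

        i1 = gen_intensity_series(0.002, 0.1, [0, 100, 200], noise_sd=0.1, seed=5)
        i2 = gen_intensity_series(0.002, 0.1, [0, 100, 200], noise_sd=0.1, seed=5)
        assert np.array_equal(i1.intensity, i2.intensity)

    def test_different_seeds_differ(self):
        n1 = gen_noe_profile(80, (30, 50), noise_sd=0.05, seed=1)
        n2 = gen_noe_profile(80, (30, 50), noise_sd=0.05, seed=2)
        assert not np.array_equal(n1.noe, n2.noe)


class TestTitrationGenerator:
    def test_noiseless_midpoint_value(self, wt_params):
        design = TitrationDesign((50.0, 100.0, 200.0, 400.0, 800.0), 1, 0.0, 0)
        series = gen_titration(wt_params, design)[0]
        at_kd = series.polarisation_mP[series.conc_uM == 100.0][0]
        assert at_kd == pytest.approx(80.0 + 0.5 * 60.0, abs=1e-12)

    def test_replicates_use_distinct_noise(self, wt_params):
        series = gen_titration(wt_params, TitrationDesign.log_spaced(seed=0))
        assert not np.array_equal(series[0].polarisation_mP, series[1].polarisation_mP)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="positive"):
            TitrationDesign((0.0, 1.0), 1, 0.0, 0)
        with pytest.raises(ValueError, match="increasing"):
            TitrationDesign((10.0, 5.0), 1, 0.0, 0)
        with pytest.raises(ValueError):
            DimerModelParams(kd=-5.0, p_base=80.0, dp_max=60.0)


class TestNOEGenerator:
    def test_noiseless_construction(self):
        prof = gen_noe_profile(168, (101, 131), rigid_level=0.82, flexible_level=0.35,
                               noise_sd=0.0, seed=0)
        below = prof.residue_index[prof.noe < 0.6]
        assert below.min() == 101 and below.max() == 131 and below.size == 31

    def test_span_validation(self):
        with pytest.raises(ValueError, match="span"):
            gen_noe_profile(100, (90, 120))
        with pytest.raises(ValueError, match="straddle"):
            gen_noe_profile(100, (10, 20), rigid_level=0.5)

    def test_values_clipped(self):
        prof = gen_noe_profile(200, (1, 200), flexible_level=-0.4, noise_sd=0.5, seed=0)
        assert prof.noe.min() >= -0.5 and prof.noe.max() <= 1.0


class TestShiftGenerator:
    def test_empty_layout_all_zero(self):
        prof = gen_shift_profile([], 25)
        assert np.allclose(prof.data["d_ca"], 0.0)
        assert np.allclose(prof.data["d_cb"], 0.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_shift_profile([("helix", (5, 15)), ("strand", (12, 20))], 30)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            gen_shift_profile([("turn", (5, 10))], 30)


class TestTrajectoryGenerator:
    def test_markov_occupancy_converges_to_stationary(self):
        spec = ToyDimerSpec(p_on=0.6, p_stay=0.8, seed=21)
        traj = gen_loop_trajectory(spec, 5000)
        from sas6flex import contact_occupancy

        occ = contact_occupancy(traj, "A:10-20", "B:2-8")
        # two-state Markov chain standard error with autocorrelation
        p_on, p_stay = 0.6, 0.8
        p01 = p_on * (1 - p_stay) / (1 - p_on)
        lam = p_stay - p01
        se = np.sqrt(p_on * (1 - p_on) / 5000 * (1 + lam) / (1 - lam))
        dev = np.abs(occ.marginal_a["occupancy_any"] - p_on)
        assert np.all(dev <= 3 * se)

    def test_contact_geometry_respects_cutoffs(self):
        spec = ToyDimerSpec(p_on=1.0, p_stay=1.0, seed=0)
        traj = gen_loop_trajectory(spec, 5)
        from sas6flex import residue_min_distance

        # planted partner of loop residue 10 is target residue 2
        assert residue_min_distance(traj, 0, ("A", 10), ("B", 2)) < spec.contact_distance_on
        off = gen_loop_trajectory(ToyDimerSpec(p_on=0.0, seed=0), 5)
        assert residue_min_distance(off, 0, ("A", 10), ("B", 2)) > 2 * spec.contact_distance_on

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            ToyDimerSpec(loop_span=(5, 15), target_region=(10, 20))
        with pytest.raises(ValueError, match="bounds"):
            ToyDimerSpec(loop_span=(25, 40), n_core_residues=30)
        with pytest.raises(ValueError, match="infeasible"):
            # stationary 0.9 with persistence 0.1 needs off->on prob > 1
            gen_loop_trajectory(ToyDimerSpec(p_on=0.9, p_stay=0.1), 10)


class TestPullGenerator:
    def test_quasi_static_limit_tracks_restraint(self):
        spec = AdhesionSpec(temperature=0.0, well_depth=0.0, n_steps=1000)
        trace = gen_pull_trace(spec, k=1000.0, v=1.0)
        # after the initial transient the CV trails λ by the friction lag γv/k
        lag_A = spec.friction * 0.1 / 1000.0 * 10.0
        tail = slice(200, None)
        assert np.allclose(trace.lambda_A[tail] - trace.cv_A[tail], lag_A, atol=0.02)

    def test_friction_only_work_baseline(self):
        from sas6flex import work_curve

        spec = AdhesionSpec(temperature=0.0, well_depth=0.0, n_steps=2000)
        w = work_curve(gen_pull_trace(spec)).final_work
        baseline = spec.friction * 0.1 * 2.0  # γ v D over 2 nm
        assert w == pytest.approx(baseline, rel=0.05)

    def test_adhesion_raises_work_in_matched_pairs(self):
        from sas6flex import work_curve

        for seed in range(4):
            with_adh = gen_pull_trace(AdhesionSpec(extra_adhesion_depth=20.0, seed=seed))
            without = gen_pull_trace(AdhesionSpec(extra_adhesion_depth=0.0, seed=seed))
            assert work_curve(with_adh).final_work > work_curve(without).final_work

    def test_unstable_timestep_rejected(self):
        with pytest.raises(ValueError, match="friction/k"):
            gen_pull_trace(AdhesionSpec(dt=0.2, friction=100.0), k=1000.0)

    def test_adhesion_spec_validation(self):
        with pytest.raises(ValueError):
            AdhesionSpec(well_depth=-1.0)
        with pytest.raises(ValueError):
            AdhesionSpec(dt=0.0)


def test_intensity_generator_flat_and_sloped():
    flat = gen_intensity_series(0.0, 0.4, [0, 100, 200, 300], noise_sd=0.0)
    assert np.allclose(flat.intensity, 0.4)
    sloped = gen_intensity_series(0.002, 0.1, [0, 100, 200, 300], noise_sd=0.0)
    assert np.allclose(np.diff(sloped.intensity), 0.2)
    with pytest.raises(ValueError, match="increasing"):
        gen_intensity_series(0.0, 0.4, [100, 50])
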
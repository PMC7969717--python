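import numpy as np
import pytest

from npbind.conformation import compute_lambda, lambda_series, superpose
from npbind.io_model import SelectionSpec
from npbind.surface import electrostatic_map, surface_points
from npbind.synthetic import (DEFAULT_PATTERNS, ParticleSpec, TrajectorySpec,
                              TwoStateSpec, make_complex, make_particle,
                              make_trajectory, make_two_state_references,
                              merge_structures, particle_as_structure)


class TestTwoStateReferences:
    def test_seeded_determinism_is_bitwise(self):
        spec = TwoStateSpec(5, 5, 90.0, 3.0, seed=1)
        a = make_two_state_references(spec)
        b = make_two_state_references(spec)
        np.testing.assert_array_equal(a.v1.coords, b.v1.coords)
        np.testing.assert_array_equal(a.v2.coords, b.v2.coords)

    @pytest.mark.parametrize("seed", [0, 3, 17])
    def test_lambda_endpoints_for_any_generated_pair(self, seed):
        refs = make_two_state_references(TwoStateSpec(seed=seed))
        assert compute_lambda(refs.v1, refs) == pytest.approx(0.0, abs=1e-12)
        assert compute_lambda(refs.v2, refs) == 1.0

    def test_n_domain_is_identical_between_states(self):
        spec = TwoStateSpec(n_residues_N_domain=8, n_residues_C_domain=6,
                            seed=2)
        refs = make_two_state_references(spec)
        np.testing.assert_array_equal(refs.v1.coords[:8], refs.v2.coords[:8])
        assert np.abs(refs.v1.coords[8:] - refs.v2.coords[8:]).max() > 0.1

    def test_c_domain_motion_is_rigid(self):
        refs = make_two_state_references(TwoStateSpec(seed=4))
        n1 = refs.v1.metadata["n_domain"][1]
        sel = SelectionSpec("residue_range", start=n1 + 1,
                            stop=len(refs.v1.atoms))
        _, rmsd = superpose(refs.v2, refs.v1, sel)
        assert rmsd < 1e-9

    def test_degenerate_and_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            TwoStateSpec(rotation_angle=0.0, translation=0.0)
        with pytest.raises(ValueError, match="3 residues"):
            TwoStateSpec(n_residues_N_domain=2)
        with pytest.raises(ValueError, match="0, 180"):
            TwoStateSpec(rotation_angle=270.0)


class TestTrajectories:
    def test_noise_free_frames_sit_exactly_at_target(self, refs):
        traj = make_trajectory(refs, TrajectorySpec(
            lambda_target=0.5, positional_noise_sd=0.0, n_frames=4, seed=0,
            rigid_scatter=False))
        for f in traj.frames:
            assert compute_lambda(f, refs) == pytest.approx(0.5, abs=1e-10)

    def test_rigid_scatter_does_not_move_lambda(self, refs):
        traj = make_trajectory(refs, TrajectorySpec(
            lambda_target=0.65, positional_noise_sd=0.0, n_frames=4, seed=1,
            rigid_scatter=True))
        for f in traj.frames:
            assert compute_lambda(f, refs) == pytest.approx(0.65, abs=1e-9)

    def test_seeded_determinism(self, refs):
        spec = TrajectorySpec(lambda_target=0.3, positional_noise_sd=0.5,
                              n_frames=5, seed=7)
        t1 = make_trajectory(refs, spec)
        t2 = make_trajectory(refs, spec)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_noisy_mean_within_3se_of_brute_force_oracle(self, refs):
        """The package's series mean must agree with a direct norm-ratio
        evaluation on the same frames (same ensemble, independent code)."""
        traj = make_trajectory(refs, TrajectorySpec(
            lambda_target=0.3, positional_noise_sd=0.5, n_frames=500, seed=5))
        series = lambda_series(traj, refs)
        sel = refs.selection.resolve(refs.v1)
        x1 = refs.v1.coords[sel].ravel()
        x2 = refs.v2_aligned.coords[sel].ravel()
        denom = np.linalg.norm(x2 - x1)
        oracle = np.array([
            np.linalg.norm(
                superpose(f, refs.v1, refs.selection)[0].coords[sel].ravel()
                - x1) / denom
            for f in traj.frames
        ])
        se = oracle.std(ddof=1) / np.sqrt(len(oracle))
        assert abs(series.mean - oracle.mean()) <= max(3 * se, 1e-12)

    def test_bias_vanishes_as_noise_vanishes(self, refs):
        """Mean lambda converges to the target as the noise shrinks."""
        biases = []
        for sd in (0.5, 0.1, 0.02, 0.0):
            traj = make_trajectory(refs, TrajectorySpec(
                lambda_target=0.4, positional_noise_sd=sd, n_frames=60,
                seed=3))
            biases.append(abs(lambda_series(traj, refs).mean - 0.4))
        assert biases[-1] < 1e-9
        assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(biases, biases[1:]))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="lambda_target"):
            TrajectorySpec(lambda_target=1.5)
        with pytest.raises(ValueError, match="noise"):
            TrajectorySpec(positional_noise_sd=-1.0)
        with pytest.raises(ValueError, match="n_frames"):
            TrajectorySpec(n_frames=0)


class TestParticles:
    def test_uniform_pattern_total_charge_is_site_count_times_q(self):
        spec = ParticleSpec(shape="sphere", seed=1,
                            site_charge_pattern=(("all", 0.25),))
        p = make_particle(spec)
        assert p.total_charge == pytest.approx(0.25 * p.n_sites, rel=1e-12)

    def test_seeded_determinism(self):
        spec = ParticleSpec(shape="needle", seed=6)
        a, b = make_particle(spec), make_particle(spec)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.charges, b.charges)

    def test_needle_tips_positive_body_negative_on_surface(self):
        p = make_particle(ParticleSpec(shape="needle", seed=1))
        pts = surface_points(p, density=0.4)
        emap = electrostatic_map(p, pts, density=0.4)
        z = pts[:, 2]
        tip_region = np.abs(z) > np.abs(z).max() * 2.0 / 3.0
        assert emap.potentials[tip_region].mean() > 0
        assert emap.potentials[~tip_region].mean() < 0

    def test_sphere_charge_per_area_stable_across_sizes(self):
        dens = []
        for size in (1.926, 3.2):
            spec = ParticleSpec(shape="sphere", characteristic_size=size,
                                seed=2)
            p = make_particle(spec)
            from npbind.synthetic import nominal_area
            dens.append(p.total_charge / nominal_area(spec))
        assert abs(dens[1] - dens[0]) / abs(np.mean(dens)) < 0.10

    def test_default_sphere_diameter_and_net_signs(self):
        sphere = make_particle(ParticleSpec(shape="sphere", seed=0))
        extent = sphere.positions.max(0) - sphere.positions.min(0)
        assert np.max(extent) <= 19.26 + 1.0       # within the 1.926 nm ball
        assert sphere.total_charge < 0             # net negative
        rod = make_particle(ParticleSpec(shape="rod", seed=0))
        assert rod.total_charge > 0                # weakly positive
        needle = make_particle(ParticleSpec(shape="needle", seed=0))
        assert needle.total_charge < 0             # negative body dominates

    def test_too_coarse_lattice_rejected(self):
        with pytest.raises(ValueError, match="lattice_spacing"):
            make_particle(ParticleSpec(shape="sphere", characteristic_size=0.4,
                                       lattice_spacing=9.0))

    def test_unknown_shape_and_region_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ParticleSpec(shape="cube")
        with pytest.raises(ValueError, match="region"):
            make_particle(ParticleSpec(shape="sphere",
                                       site_charge_pattern=(("edge", 1.0),)))


class TestComplexFixture:
    def test_same_seed_reproduces_fixture_bitwise(self):
        p1, n1, t1 = make_complex(3)
        p2, n2, t2 = make_complex(3)
        np.testing.assert_array_equal(p1.coords, p2.coords)
        np.testing.assert_array_equal(n1.positions, n2.positions)
        assert t1.rows.equals(t2.rows)

    def test_total_charge_is_sum_of_parts(self, complex_fixture):
        protein, particle, _, comp = complex_fixture
        assert comp.total_charge() == pytest.approx(
            protein.total_charge() + particle.total_charge, abs=1e-9)

    def test_fixture_is_fully_parameterized(self, complex_fixture):
        _, _, _, comp = complex_fixture
        for a in comp.atoms:
            assert a.charge is not None and a.lj_sigma is not None
            assert a.lj_epsilon is not None and a.radius is not None

    def test_fixture_has_an_attractive_contact_region(self, wt_binding):
        # at least one protein residue pulls the particle in
        protein_terms = wt_binding.per_residue[
            [k.startswith("A:") for k in wt_binding.per_residue.index]]
        assert protein_terms.min() < -0.5
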
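"""Tests for PCA gating, energy decomposition, dipole correlations and
ion partition profiles."""

import numpy as np
import pytest

from crownbind.ensemble import (
    ConformationEnsemble,
    EllipseGate,
    ParticleFrame,
    angle_density,
    assign_gates,
    cluster_dipole_angle,
    fit_gates,
    gate_probabilities,
    mean_site_separation,
    minimum_image,
    partition_profile,
    pca_project,
    weighted_energy_decomposition,
)


def make_frame(waters, dipoles, sites, box=40.0, receptor=None, ions=None, species=()):
    b = np.full(3, box)
    return ParticleFrame(
        receptor=receptor if receptor is not None else np.array([[20.0, 20.0, 20.0]]),
        ions=ions if ions is not None else np.empty((0, 3)),
        ion_species=species,
        waters=np.asarray(waters, float),
        water_dipoles=np.asarray(dipoles, float),
        box=b,
        sites=np.asarray(sites, float),
    )


class TestPCA:
    def test_recovers_embedded_two_dim_structure(self):
        rng = np.random.default_rng(0)
        n = 4000
        signal = rng.normal(0, [3.0, 1.5], size=(n, 2))
        basis = np.linalg.qr(rng.normal(size=(10, 10)))[0][:, :2]
        x = signal @ basis.T + rng.normal(0, 0.01, size=(n, 10))
        res = pca_project(x, 2)
        var = signal.var(axis=0).sum() + 0.01**2 * 10
        assert res.explained_variance_ratio[0] == pytest.approx(
            signal[:, 0].var() / var, rel=0.05
        )
        assert res.explained_variance_ratio[1] == pytest.approx(
            signal[:, 1].var() / var, rel=0.05
        )

    def test_isotropic_data_splits_variance_evenly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6000, 5))
        res = pca_project(x, 2)
        assert np.all(np.abs(res.explained_variance_ratio - 0.2) < 0.03)

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 4))
        res = pca_project(x, 4)
        np.testing.assert_allclose(res.reconstruct(), x, atol=1e-10)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, [5.0, 1.0, 0.1], size=(500, 3))
        comps = pca_project(x, 2).components
        for c in comps:
            assert c[np.argmax(np.abs(c))] > 0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca_project(np.ones((10, 3)), 2)


class TestGates:
    def test_rotated_ellipse_contains(self):
        gate = EllipseGate("g", center=(0.0, 0.0), semi_axes=(2.0, 0.5), angle_deg=90.0)
        assert gate.contains(np.array([[0.0, 1.9]]))[0]
        assert not gate.contains(np.array([[1.0, 0.0]]))[0]

    def test_assign_first_match_and_rest(self):
        gates = [
            EllipseGate("a", (0.0, 0.0), (1.0, 1.0)),
            EllipseGate("b", (3.0, 0.0), (1.0, 1.0)),
        ]
        labels = assign_gates(np.array([[0.1, 0.0], [3.0, 0.2], [10.0, 0.0]]), gates)
        assert list(labels) == ["a", "b", "rest"]

    def test_probabilities_partition_exactly(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 3, size=(5000, 2))
        gates = [
            EllipseGate("a", (0.0, 0.0), (1.0, 1.0)),
            EllipseGate("b", (4.0, 0.0), (1.5, 1.0)),
        ]
        probs = gate_probabilities(pts, gates)
        assert probs.p.sum() + probs.p_rest == pytest.approx(1.0, abs=1e-12)

    def test_gate_containing_everything(self):
        pts = np.random.default_rng(5).normal(0, 0.1, size=(1000, 2))
        probs = gate_probabilities(pts, [EllipseGate("all", (0.0, 0.0), (50.0, 50.0))])
        assert probs.p[0] == pytest.approx(1.0, abs=1e-12)
        assert probs.se[0] == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_gates_warn(self):
        pts = np.zeros((100, 2))
        gates = [
            EllipseGate("a", (0.0, 0.0), (1.0, 1.0)),
            EllipseGate("b", (0.5, 0.0), (1.0, 1.0)),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            gate_probabilities(pts, gates)

    def test_block_se_consistent_with_multinomial(self):
        """On exchangeable frames the block-averaged SE should match the
        multinomial standard error within a factor of two."""
        rng = np.random.default_rng(6)
        n = 20000
        pts = np.where(
            (rng.random(n) < 0.3)[:, None],
            rng.normal(0, 0.2, (n, 2)),
            rng.normal(5, 0.2, (n, 2)),
        )
        probs = gate_probabilities(pts, [EllipseGate("a", (0.0, 0.0), (1.5, 1.5))])
        multinomial = np.sqrt(probs.p[0] * (1 - probs.p[0]) / n)
        assert 0.5 < probs.se[0] / multinomial < 2.0

    def test_fit_gates_recovers_cluster_centers(self):
        rng = np.random.default_rng(7)
        pts = np.vstack(
            [rng.normal(c, 0.3, size=(500, 2)) for c in ((-4.0, 0.0), (0.0, 2.0), (4.0, 0.0))]
        )
        gates = fit_gates(pts, 3, labels=["l", "m", "r"])
        centers = np.array([g.center for g in gates])
        np.testing.assert_allclose(centers[:, 0], [-4.0, 0.0, 4.0], atol=0.15)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            gate_probabilities(np.empty((0, 2)), [EllipseGate("a", (0, 0), (1, 1))])


class TestEnergyDecomposition:
    @staticmethod
    def _toy(states):
        ensembles, assignments = {}, {}
        for state, spec in states.items():
            labels, energies = [], []
            for name, (n, u) in spec.items():
                labels += [name] * n
                energies += [u] * n
            ensembles[state] = ConformationEnsemble(
                descriptors=np.zeros((len(labels), 2)),
                energies=np.array(energies),
                bound_state=state,
            )
            assignments[state] = np.array(labels, dtype=object)
        return ensembles, assignments

    def test_hand_arithmetic_two_conformations(self):
        ens, asg = self._toy(
            {
                0: {"A": (3, 0.0), "B": (1, 4.0)},
                1: {"A": (2, -10.0), "B": (2, -6.0)},
                2: {"A": (1, -20.0), "B": (3, -18.0)},
            }
        )
        deco = weighted_energy_decomposition(ens, asg, ["A", "B"])
        assert deco.u[0] == pytest.approx(1.0)
        assert deco.u[1] == pytest.approx(-8.0)
        assert deco.u[2] == pytest.approx(-18.5)
        assert deco.ddu == pytest.approx((-18.5 + 8.0) - (-8.0 - 1.0))

    def test_weighted_sum_identity_and_running_sum(self):
        rng = np.random.default_rng(8)
        ens, asg = {}, {}
        for state in (0, 1, 2):
            n = 3000
            labels = rng.choice(["A", "B", "C", "rest"], size=n, p=[0.4, 0.3, 0.2, 0.1])
            ens[state] = ConformationEnsemble(
                descriptors=np.zeros((n, 2)),
                energies=rng.normal(-50.0 * state, 3.0, n),
                bound_state=state,
            )
            asg[state] = labels
        deco = weighted_energy_decomposition(ens, asg, ["A", "B", "C"])
        t = deco.table
        for state in (0, 1, 2):
            assert (t[f"p_{state}"] * t[f"U_{state}"]).sum() == pytest.approx(
                deco.u[state], abs=1e-10
            )
        assert t["running_dd_pU"].iloc[-1] == pytest.approx(deco.ddu, abs=1e-10)

    def test_single_shared_energy_is_trivial(self):
        ens, asg = self._toy(
            {0: {"A": (2, 1.0), "B": (2, 1.0)},
             1: {"A": (2, -5.0), "B": (2, -5.0)},
             2: {"A": (2, -12.0), "B": (2, -12.0)}}
        )
        deco = weighted_energy_decomposition(ens, asg, ["A", "B"])
        assert deco.table["dd_pU"].sum() == pytest.approx(deco.ddu, abs=1e-12)
        assert deco.ddu == pytest.approx(-1.0)

    def test_missing_state_rejected(self):
        ens, asg = self._toy({0: {"A": (2, 0.0)}, 1: {"A": (2, 0.0)}})
        with pytest.raises(ValueError, match="missing bound state"):
            weighted_energy_decomposition(ens, asg, ["A"])


class TestDipoleAngles:
    def test_identical_dipole_sums_give_zero(self):
        waters = np.array([[18.0, 20, 20], [19.0, 20, 20], [21.0, 20, 20], [22.0, 20, 20]] * 2)
        dipoles = np.tile([0.0, 0.0, 1.0], (8, 1))
        frame = make_frame(waters, dipoles, [[17.0, 20, 20], [23.0, 20, 20]])
        assert cluster_dipole_angle(frame) == pytest.approx(0.0, abs=1e-8)

    def test_antiparallel_sums_give_180(self):
        waters = np.vstack(
            [np.array([[15.0, 20, 20]]) + [[i, 0, 0] for i in range(4)],
             np.array([[23.0, 20, 20]]) + [[i, 0, 0] for i in range(4)]]
        )
        dipoles = np.vstack([np.tile([0, 0, 1.0], (4, 1)), np.tile([0, 0, -1.0], (4, 1))])
        frame = make_frame(waters, dipoles, [[16.0, 20, 20], [24.0, 20, 20]])
        assert cluster_dipole_angle(frame) == pytest.approx(180.0, abs=1e-8)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(9)
        box = 1000.0  # effectively non-periodic so a rigid rotation is exact
        center = np.full(3, 500.0)
        waters = center + rng.normal(0, 3, size=(30, 3))
        dipoles = rng.normal(size=(30, 3))
        sites = center + np.array([[-5.0, 0, 0], [5.0, 0, 0]])
        frame = make_frame(waters, dipoles, sites, box=box, receptor=center[None, :])
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]]
        )
        rotated = make_frame(
            (waters - center) @ rot.T + center,
            dipoles @ rot.T,
            (sites - center) @ rot.T + center,
            box=box,
            receptor=center[None, :],
        )
        assert cluster_dipole_angle(rotated) == pytest.approx(
            cluster_dipole_angle(frame), abs=1e-8
        )

    def test_zero_dipole_flagged_nan(self):
        waters = np.array([[18.0, 20, 20]] * 4 + [[22.0, 20, 20]] * 4)
        dipoles = np.zeros((8, 3))
        frame = make_frame(waters, dipoles, [[17.0, 20, 20], [23.0, 20, 20]])
        assert np.isnan(cluster_dipole_angle(frame))

    def test_too_few_waters_rejected(self):
        frame = make_frame(
            np.array([[20.0, 20, 20]]), np.array([[0.0, 0, 1]]),
            [[19.0, 20, 20], [21.0, 20, 20]],
        )
        with pytest.raises(ValueError):
            cluster_dipole_angle(frame, k=4)


class TestAngleDensity:
    def test_single_value_occupies_one_window(self):
        dens = angle_density(np.full(100, 45.0))
        assert dens.density[1] > 0
        assert np.all(np.delete(dens.density, 1) == 0)

    def test_normalization(self):
        rng = np.random.default_rng(10)
        dens = angle_density(rng.uniform(0, 180, 5000))
        width = np.deg2rad(2 * dens.window_half_width_deg)
        assert dens.density.sum() * width == pytest.approx(1.0, abs=1e-10)

    def test_nan_angles_excluded(self):
        angles = np.array([45.0] * 50 + [np.nan] * 10)
        dens = angle_density(angles)
        width = np.deg2rad(30.0)
        assert dens.density.sum() * width == pytest.approx(1.0, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            angle_density([])


class TestPartitionProfile:
    def test_uniform_distribution_gives_unity(self):
        rng = np.random.default_rng(11)
        frames = []
        for _ in range(150):
            box = 30.0
            ions = rng.random((50, 3)) * box
            waters = rng.random((500, 3)) * box
            frames.append(
                make_frame(
                    waters, np.zeros_like(waters),
                    [[10.0, 15, 15], [20.0, 15, 15]], box=box,
                    receptor=np.array([[15.0, 15, 15]]),
                    ions=ions, species=("Cl",) * 50,
                )
            )
        prof = partition_profile(frames, "Cl", [6.0, 10.0, 27.0])
        assert np.all(np.abs(prof["kp"].to_numpy()[:2] - 1.0) < 0.15)
        assert prof["kp"].iloc[-1] == 1.0  # box-spanning distance: exact

    def test_scale_invariance_under_uniform_dilution(self):
        """Duplicating every ion and water (the inverse of a uniform
        dilution) leaves K_p(d) exactly unchanged."""
        rng = np.random.default_rng(12)
        box = 24.0
        ions = rng.random((40, 3)) * box
        waters = rng.random((400, 3)) * box
        base = make_frame(
            waters, np.zeros_like(waters), [[8.0, 12, 12], [16.0, 12, 12]],
            box=box, receptor=np.array([[12.0, 12, 12]]),
            ions=ions, species=("Cl",) * 40,
        )
        doubled = make_frame(
            np.vstack([waters, waters]), np.zeros((800, 3)),
            [[8.0, 12, 12], [16.0, 12, 12]],
            box=box, receptor=np.array([[12.0, 12, 12]]),
            ions=np.vstack([ions, ions]), species=("Cl",) * 80,
        )
        grid = [4.0, 6.0, 10.0]
        p_base = partition_profile([base], "Cl", grid)["kp"].to_numpy()
        p_doubled = partition_profile([doubled], "Cl", grid)["kp"].to_numpy()
        np.testing.assert_allclose(p_doubled, p_base, rtol=1e-12)

    def test_missing_species_rejected(self):
        frame = make_frame(
            np.array([[1.0, 1, 1]]), np.zeros((1, 3)), [[0.0, 0, 0], [2.0, 0, 0]],
            ions=np.array([[3.0, 3, 3]]), species=("Cl",),
        )
        with pytest.raises(ValueError, match="species"):
            partition_profile([frame], "SCN_S", [5.0])

    def test_undefined_region_reported_nan(self):
        frame = make_frame(
            np.array([[30.0, 30, 30]]), np.zeros((1, 3)), [[0.0, 0, 0], [2.0, 0, 0]],
            box=60.0, receptor=np.array([[0.0, 0, 0]]),
            ions=np.array([[1.0, 0, 0]]), species=("Cl",),
        )
        prof = partition_profile([frame], "Cl", [2.0])
        assert np.isnan(prof["kp"].iloc[0])


class TestGeometryHelpers:
    def test_minimum_image_wraps(self):
        box = np.array([10.0, 10.0, 10.0])
        d = minimum_image(np.array([9.0, -9.0, 0.5]), box)
        np.testing.assert_allclose(d, [-1.0, 1.0, 0.5])

    def test_mean_site_separation_arithmetic(self):
        f1 = make_frame(
            np.zeros((4, 3)) + 1.0, np.zeros((4, 3)), [[0.0, 0, 0], [10.0, 0, 0]]
        )
        f2 = make_frame(
            np.zeros((4, 3)) + 1.0, np.zeros((4, 3)), [[0.0, 0, 0], [13.0, 0, 0]]
        )
        assert mean_site_separation([f1, f2]) == pytest.approx(11.5)

    def test_site_separation_uses_minimum_image(self):
        f = make_frame(
            np.zeros((4, 3)) + 1.0, np.zeros((4, 3)), [[1.0, 0, 0], [39.0, 0, 0]],
            box=40.0,
        )
        assert mean_site_separation([f]) == pytest.approx(2.0)
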
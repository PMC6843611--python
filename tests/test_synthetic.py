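import dataclasses

import numpy as np
import pytest

from memion.errors import GenerationError
from memion.synthetic import (
    CholesterolSpec,
    IFCSettings,
    SurfactantSpec,
    SyntheticSpec,
    default_role_map,
    generate_measurements,
    generate_system,
)
from memion.trajectory import REQUIRED_ROLES, Role, Species


def _spec(**kw):
    base = dict(
        n_lipids_per_leaflet=25,
        surfactants=[SurfactantSpec(species="BAC", count=9),
                     SurfactantSpec(species="SDS", count=4)],
        cholesterol=CholesterolSpec(count=10),
        n_frames=3,
        seed=17,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestGenerateSystem:
    def test_same_seed_identical_output(self, tmp_path):
        t1, m1 = generate_system(_spec())
        t2, m2 = generate_system(_spec())
        np.testing.assert_array_equal(t1.coords, t2.coords)
        m1.to_json(tmp_path / "m1.json")
        m2.to_json(tmp_path / "m2.json")
        assert (tmp_path / "m1.json").read_bytes() == (tmp_path / "m2.json").read_bytes()

    def test_different_seed_differs(self):
        t1, _ = generate_system(_spec(seed=1))
        t2, _ = generate_system(_spec(seed=2))
        assert not np.array_equal(t1.coords, t2.coords)

    def test_satisfies_analysis_preconditions(self):
        traj, _ = generate_system(_spec())
        # strictly increasing times, positive boxes
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.boxes > 0)
        # full role coverage per molecule
        per_mol = {}
        for a in traj.atoms:
            per_mol.setdefault((a.molecule_id, a.species), []).append(a.role)
        for (mol, sp), roles in per_mol.items():
            for needed in REQUIRED_ROLES.get(sp, ()):
                assert roles.count(needed) == 1, (mol, sp, needed)

    def test_counts_match_spec(self):
        traj, manifest = generate_system(_spec())
        assert len(traj.atom_index(roles=[Role.N_PLUS])) == 9
        assert len(traj.atom_index(roles=[Role.SULFATE_S])) == 4
        assert len(traj.atom_index(roles=[Role.CHOL_O])) == 10
        assert len(traj.atom_index(roles=[Role.LIPID_P])) == 50
        assert len(manifest.surfactants) == 13
        # molecules split evenly between monolayers
        upper = sum(1 for s in manifest.surfactants if s["leaflet"] == "UPPER")
        assert abs(2 * upper - 13) <= len(_spec().surfactants)

    def test_packing_failure_raises(self):
        with pytest.raises(GenerationError, match="capacity"):
            generate_system(_spec(box_edge_xy=3.0))

    def test_angle_draws_recovered_by_analysis(self):
        from memion.orientation import compute_orientation_angles

        spec = SyntheticSpec(
            n_lipids_per_leaflet=64,
            surfactants=[SurfactantSpec(species="KOR105", count=100,
                                        eta0_deg=130.0, theta0_deg=150.0,
                                        kappa=8.0)],
            roughness_sigma=0.0,    # no jitter: angles must match draws exactly
            n_frames=2,
            seed=23,
        )
        traj, manifest = generate_system(spec)
        rec = compute_orientation_angles(traj)
        drawn = {s["molecule_id"]: s for s in manifest.surfactants}
        for _, row in rec.iterrows():
            assert row.eta_deg == pytest.approx(
                drawn[row.molecule_id]["eta_deg"], abs=1e-9
            )
            assert row.theta_deg == pytest.approx(
                drawn[row.molecule_id]["theta_deg"], abs=1e-9
            )

    def test_realized_angle_moments_near_prescribed(self):
        spec = SyntheticSpec(
            n_lipids_per_leaflet=64,
            surfactants=[SurfactantSpec(species="KOR105", count=2000,
                                        eta0_deg=130.0, theta0_deg=150.0,
                                        kappa=8.0)],
            n_frames=1,
            seed=29,
        )
        _, manifest = generate_system(spec)
        etas = np.array([s["eta_deg"] for s in manifest.surfactants])
        se = etas.std(ddof=1) / np.sqrt(len(etas))
        assert abs(etas.mean() - 130.0) < 3 * se

    def test_cholesterol_clustering_is_short_ranged(self):
        # offspring within ~sigma of a shared parent: nearest-neighbour
        # distances far below the uniform expectation
        spec = _spec(cholesterol=CholesterolSpec(
            count=30, thomas_parent_rate=0.005, offspring_sigma=0.2))
        traj, manifest = generate_system(spec)
        pos = traj.coords[0][traj.atom_index(roles=[Role.CHOL_O])][:, :2]
        box = traj.boxes[0][0]
        d = pos[:, None] - pos[None, :]
        d -= box * np.round(d / box)
        dist = np.sqrt((d ** 2).sum(-1)) + np.eye(len(pos)) * 1e9
        nn = dist.min(axis=1)
        # uniform points at this density would have mean NN spacing
        # ~ 0.5 / sqrt(rho) per leaflet; clustered ones sit much closer
        rho = (len(pos) / 2) / box ** 2
        assert np.median(nn) < 0.5 * 0.5 / np.sqrt(rho)

    def test_pure_bilayer_has_expected_charge_planes(self):
        from memion.charge_profile import compute_charge_profile, find_extrema

        spec = SyntheticSpec(n_lipids_per_leaflet=64, n_frames=10, seed=31)
        traj, _ = generate_system(spec)
        prof = compute_charge_profile(
            traj, {"P": {"roles": [Role.LIPID_P]}, "N": {"roles": [Role.LIPID_N]}}
        )
        neg = find_extrema(prof, "P").negative()
        pos = find_extrema(prof, "N").positive()
        assert sorted(round(abs(p.z_position), 1) for p in neg) == [1.8, 1.8]
        assert sorted(round(abs(p.z_position), 1) for p in pos) == [1.9, 1.9]


class TestGenerateMeasurements:
    def _params(self):
        from memion.electrostatics import AdsorptionParams, ElectrolyteConditions

        return (
            AdsorptionParams(binding_constant=1e5, max_site_density=0.05,
                             surfactant_valence=1),
            ElectrolyteConditions(),
            np.geomspace(1.0, 100.0, 8),
        )

    def test_zero_noise_equals_model(self):
        from memion.electrostatics import adsorption_curve

        params, cond, conc = self._params()
        curve, scans, true_curve = generate_measurements(
            params, cond, conc, noise_sd_mV=0.0,
            ifc=IFCSettings(noise_sd=0.0), seed=0,
        )
        model = adsorption_curve(params, cond, conc)
        np.testing.assert_array_equal(curve.delta_phi_mV, model.delta_phi_mV)
        np.testing.assert_array_equal(true_curve.delta_phi_mV, model.delta_phi_mV)

    def test_scan_vertices_at_noisy_potentials(self):
        from memion.electrostatics import estimate_phi_in

        params, cond, conc = self._params()
        curve, scans, _ = generate_measurements(
            params, cond, conc, noise_sd_mV=2.0,
            ifc=IFCSettings(noise_sd=0.0), seed=5,
        )
        re_phi = np.array([estimate_phi_in(s).phi_in_mV for s in scans])
        np.testing.assert_allclose(re_phi, curve.delta_phi_mV, atol=1e-6)

    def test_fit_recovers_parameters(self):
        from memion.electrostatics import fit_adsorption

        params, cond, conc = self._params()
        curve, _, _ = generate_measurements(
            params, cond, conc, noise_sd_mV=1.0, seed=3,
        )
        fit = fit_adsorption(curve, cond, valence=1)
        assert fit.identifiable
        assert abs(fit.params.binding_constant / 1e5 - 1) < 0.5

    def test_deterministic_under_seed(self):
        params, cond, conc = self._params()
        c1, s1, _ = generate_measurements(params, cond, conc, seed=9)
        c2, s2, _ = generate_measurements(params, cond, conc, seed=9)
        np.testing.assert_array_equal(c1.delta_phi_mV, c2.delta_phi_mV)
        np.testing.assert_array_equal(s1[0].capacitance, s2[0].capacitance)


def test_default_role_map_covers_generated_names():
    rm = default_role_map()
    for sp in (Species.DOPC, Species.CHOL, Species.KOR105, Species.BAC,
               Species.SDS):
        assert sp in rm
        roles = {e["role"] for e in rm[sp].values()}
        for needed in REQUIRED_ROLES[sp]:
            assert needed in roles
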
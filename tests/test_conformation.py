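"""Dihedrals, local PCA, PC1 free-energy profiles and the dA_conf feature."""
import math

import numpy as np
import pytest

from deamidkit import conformation as conf
from deamidkit import synthetic_fixtures as sf
from deamidkit.ensemble_io import AsnSite

from conftest import bare_ensemble

KT310 = conf.KB_KCAL_MOL_K * 310.0


def _fragment_ensemble(frames, box=5.0):
    """(n_frames, 10, 3) fragment-only ensemble with canonical atom names."""
    names = ["N", "CA", "CB", "CG", "ND2", "OD1", "C", "O", "N", "CA"]
    elements = ["N", "C", "C", "C", "N", "O", "C", "O", "N", "C"]
    resnames = ["ASN"] * 8 + ["GLY"] * 2
    resids = [1] * 8 + [2] * 2
    ens = bare_ensemble(np.asarray(frames) + box / 2, names, resnames, resids,
                        elements=elements, box=box)
    site = AsnSite(
        protein_id="t", asn_residue=1, next_residue_name="GLY",
        fragment_atoms=np.arange(10), segment_atoms=np.array([1, 6, 7, 8, 9]),
        n1_N=8,
    )
    return ens, site


class TestDihedrals:
    def test_planar_cis_and_trans(self):
        cis = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        trans = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
        from deamidkit._geometry import dihedral
        assert dihedral(*cis) == pytest.approx(0.0, abs=1e-9)
        assert dihedral(*trans) == pytest.approx(180.0, abs=1e-9)

    def test_against_mdtraj_oracle(self):
        """Random quadruples agree with mdtraj's dihedral implementation."""
        import mdtraj as md
        from deamidkit._geometry import dihedral

        rng = np.random.default_rng(10)
        pts = rng.normal(size=(50, 4, 3))
        mine = dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("ALA", chain)
        for i in range(4):
            top.add_atom(f"C{i}", md.element.carbon, res)
        ref = np.degrees(md.compute_dihedrals(md.Trajectory(pts, top), [[0, 1, 2, 3]])[:, 0])
        # mdtraj computes in float32
        np.testing.assert_allclose(mine, ref, atol=5e-4)

    def test_monitor_reports_expected_series(self):
        rng = np.random.default_rng(1)
        frames = sf.base_fragment_geometry() + rng.normal(0, 0.01, size=(20, 10, 3))
        ens, site = _fragment_ensemble(frames)
        out = conf.monitor_dihedrals(ens, site)
        for key in ("psi", "chi1", "chi2", "delta", "d_NCgamma"):
            assert key in out and out[key].shape == (20,)
        assert "phi" not in out  # N-terminal Asn: no n-1 residue
        assert np.all(out["d_NCgamma"] > 0)
        for key in ("psi", "chi1", "chi2", "delta"):
            assert np.all((out[key] > -180.0) & (out[key] <= 180.0))


class TestLocalPca:
    def test_isotropic_jitter_reference_at_origin(self, refs):
        rng = np.random.default_rng(2)
        sigma = 0.004
        frames = refs.R_geometry + rng.normal(0, sigma, size=(4000, 10, 3))
        ens, site = _fragment_ensemble(frames)
        model = conf.local_pca(ens, [site], refs.R_geometry)
        assert abs(model.reference_projection[0]) < 5 * sigma / math.sqrt(10)
        # fitting removes 6 rigid-body dof; the rest carry ~sigma^2 each
        assert model.eigenvalues[0] == pytest.approx(sigma**2, rel=0.3)

    def test_planted_mode_recovered(self, refs):
        """A single planted 30-vector displacement dominates PC1."""
        rng = np.random.default_rng(3)
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        amp = rng.normal(0, 0.05, size=2000)
        frames = refs.R_geometry[None] + amp[:, None, None] * v.reshape(1, 10, 3)
        frames = frames + rng.normal(0, 0.001, size=frames.shape)
        ens, site = _fragment_ensemble(frames)
        model = conf.local_pca(ens, [site], refs.R_geometry)
        # compare in the fitted frame: fit the displaced geometry and diff
        from deamidkit._geometry import kabsch_fit
        plus = kabsch_fit(refs.R_geometry + 0.05 * v.reshape(10, 3), refs.R_geometry)
        direction = (plus - refs.R_geometry).reshape(-1)
        direction /= np.linalg.norm(direction)
        cosine = abs(direction @ model.eigenvectors[:, 0])
        assert cosine > 0.99

    def test_duplication_invariance(self, refs):
        rng = np.random.default_rng(4)
        frames = refs.R_geometry + rng.normal(0, 0.01, size=(200, 10, 3))
        ens1, site = _fragment_ensemble(frames)
        ens2, _ = _fragment_ensemble(np.concatenate([frames, frames]))
        m1 = conf.local_pca(ens1, [site], refs.R_geometry)
        m2 = conf.local_pca(ens2, [site], refs.R_geometry)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-12)
        # leading, non-degenerate eigenvectors agree (trailing near-zero
        # eigenvalues span an arbitrary basis)
        for k in range(2):
            assert abs(m1.eigenvectors[:, k] @ m2.eigenvectors[:, k]) == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_and_trace_conserved(self, refs):
        rng = np.random.default_rng(5)
        frames = refs.R_geometry + rng.normal(0, 0.02, size=(300, 10, 3))
        ens, site = _fragment_ensemble(frames)
        model = conf.local_pca(ens, [site], refs.R_geometry)
        gram = model.eigenvectors.T @ model.eigenvectors
        np.testing.assert_allclose(gram, np.eye(30), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-15)
        # eigenvalue sum equals total variance of the fitted coordinates
        from deamidkit.conformation import _fit_and_flatten
        flat = _fit_and_flatten(ens.coords[:, site.fragment_atoms], refs.R_geometry)
        total_var = np.sum(np.var(flat, axis=0))
        assert np.sum(model.eigenvalues) == pytest.approx(total_var, rel=1e-8)

    def test_single_frame_rejected(self, refs):
        ens, site = _fragment_ensemble(refs.R_geometry[None])
        with pytest.raises(conf.DegenerateInputError):
            conf.local_pca(ens, [site], refs.R_geometry)

    def test_profile_invariant_under_rigid_motion(self, refs):
        """Superposition removes global rotation/translation."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(6)
        frames = refs.R_geometry + rng.normal(0, 0.01, size=(500, 10, 3))
        moved = np.empty_like(frames)
        for i in range(len(frames)):
            R = Rotation.random(rng=rng).as_matrix()
            moved[i] = frames[i] @ R.T + rng.uniform(-0.5, 0.5, 3)
        ens1, site = _fragment_ensemble(frames)
        ens2, _ = _fragment_ensemble(moved)
        m1 = conf.local_pca(ens1, [site], refs.R_geometry)
        m2 = conf.local_pca(ens2, [site], refs.R_geometry)
        p1 = m1.project(ens1.coords[:, site.fragment_atoms], 1)[:, 0]
        p2 = m2.project(ens2.coords[:, site.fragment_atoms], 1)[:, 0]
        f1 = conf.free_energy_profile(p1, bin_width=0.005)
        f2 = conf.free_energy_profile(p2, bin_width=0.005)
        # same occupied-bin free energies (up to PC sign, handled by |PC1|)
        v1 = np.sort(f1.deltaA[~f1.empty_bins])
        v2 = np.sort(f2.deltaA[~f2.empty_bins])
        np.testing.assert_allclose(v1, v2, atol=1e-9)


class TestFreeEnergy:
    def test_two_state_closed_form(self):
        """Populations 0.8/0.2 at 310 K give dA gap -kT ln(0.25) = 0.854."""
        rng = np.random.default_rng(7)
        n = 50_000
        # states sit at bin centres so the histogram does not split a peak
        pc1 = np.where(rng.uniform(size=n) < 0.8, 0.0125, 0.0625)
        pc1 = pc1 + rng.normal(0, 1e-4, size=n)
        prof = conf.free_energy_profile(pc1, temperature=310.0, bin_width=0.005)
        gap = prof.value_at(0.0625) - prof.value_at(0.0125)
        assert gap == pytest.approx(-KT310 * math.log(0.2 / 0.8), abs=0.02)
        assert prof.value_at(0.0125) == 0.0

    def test_single_bin_profile_is_zero(self):
        prof = conf.free_energy_profile(np.full(100, 0.013), bin_width=0.005)
        occupied = ~prof.empty_bins
        assert occupied.sum() == 1
        assert prof.deltaA[occupied][0] == 0.0

    def test_uniform_occupancy_flat(self):
        rng = np.random.default_rng(8)
        pc1 = rng.uniform(-0.05, 0.05, size=200_000)
        prof = conf.free_energy_profile(pc1, bin_width=0.01)
        inner = prof.deltaA[~prof.empty_bins]
        assert np.nanmax(inner) < 0.05

    def test_min_is_zero_and_nonnegative(self):
        rng = np.random.default_rng(9)
        prof = conf.free_energy_profile(rng.normal(0, 0.02, 5000))
        vals = prof.deltaA[~prof.empty_bins]
        assert vals.min() == 0.0
        assert np.all(vals >= 0.0)


class TestConfFeature:
    def _profile_from(self, pc1, T=310.0):
        return conf.free_energy_profile(np.asarray(pc1), temperature=T)

    def test_arithmetic_mean_of_readings(self):
        """Readings {1,1,2,2} kcal/mol average to 1.5."""
        # bins containing +-0.02 / +-0.05 get populations chosen so their
        # Boltzmann-inverted values are exactly 1 and 2 kcal/mol
        kT = KT310
        n0 = 100_000
        samples = [np.full(n0, 0.0025)]
        for centers, dA in (((0.0225, -0.0175), 1.0), ((0.0525, -0.0475), 2.0)):
            n = int(round(n0 * math.exp(-dA / kT)))
            for c in centers:
                samples.append(np.full(n, c))
        pc1 = np.concatenate(samples)
        prof = self._profile_from(pc1)
        feat = conf.conf_free_energy_feature({"R": prof, "Rstar": prof})
        assert feat == pytest.approx(1.5, abs=1e-3)

    def test_jitter_around_reference_near_zero(self, refs):
        rng = np.random.default_rng(11)
        pc1 = rng.normal(0, 0.04, size=20_000)
        prof = self._profile_from(pc1)
        feat = conf.conf_free_energy_feature({"R": prof, "Rstar": prof})
        # minimum at the reference: targeted readings are small
        assert feat < 1.5

    def test_sentinel_when_targets_never_visited(self):
        prof = self._profile_from(np.random.default_rng(12).normal(0, 0.002, 1000))
        feat = conf.conf_free_energy_feature({"R": prof, "Rstar": prof})
        assert feat == conf.CONF_SENTINEL

    def test_mismatched_temperatures_rejected(self):
        p1 = self._profile_from([0.0, 0.02], T=310.0)
        p2 = self._profile_from([0.0, 0.02], T=300.0)
        with pytest.raises(ValueError):
            conf.conf_free_energy_feature({"R": p1, "Rstar": p2})


class TestSubspaceConvergence:
    def _model(self, evecs):
        return conf.LocalPcaModel(
            mean=np.zeros(30), eigenvectors=evecs,
            eigenvalues=np.linspace(1, 0.01, 30),
            reference_projection=(0.0, 0.0), variance_fraction_2pc=0.5,
            reference=np.zeros((10, 3)),
        )

    def test_identical_replicates_give_one(self):
        q, _ = np.linalg.qr(np.random.default_rng(13).normal(size=(30, 30)))
        assert conf.subspace_convergence([self._model(q), self._model(q)]) == pytest.approx(1.0)

    def test_orthogonal_modes_give_zero(self):
        q, _ = np.linalg.qr(np.random.default_rng(14).normal(size=(30, 30)))
        q2 = q.copy()
        q2[:, [0, 1, 2, 3]] = q[:, [2, 3, 0, 1]]
        assert conf.subspace_convergence([self._model(q), self._model(q2)]) == pytest.approx(0.0, abs=1e-12)

    def test_split_halves_consistent(self, refs):
        rng = np.random.default_rng(15)
        v = rng.normal(size=(30, 2))
        frames = refs.R_geometry[None] + (
            rng.normal(0, 0.04, size=(4000, 2)) @ v.T
        ).reshape(-1, 10, 3) + rng.normal(0, 0.002, size=(4000, 10, 3))
        ens_a, site = _fragment_ensemble(frames[:2000])
        ens_b, _ = _fragment_ensemble(frames[2000:])
        m_a = conf.local_pca(ens_a, [site], refs.R_geometry)
        m_b = conf.local_pca(ens_b, [site], refs.R_geometry)
        assert conf.subspace_convergence([m_a, m_b]) > 0.9


class TestReferenceStates:
    def test_json_round_trip_and_debye_conversion(self, tmp_path, refs):
        p = tmp_path / "refs.json"
        refs.to_json(p)
        back = conf.ReferenceStates.from_json(p)
        np.testing.assert_allclose(back.R_geometry, refs.R_geometry)
        np.testing.assert_allclose(back.mu_TS, refs.mu_TS)
        # debye-declared file converts on read
        import json
        doc = json.loads(p.read_text())
        doc["dipole_units"] = "debye"
        p2 = tmp_path / "refs_debye.json"
        p2.write_text(json.dumps(doc))
        deb = conf.ReferenceStates.from_json(p2)
        np.testing.assert_allclose(deb.mu_R, refs.mu_R * conf.DEBYE_TO_E_NM)

    def test_rstar_differs_only_in_ring_distance(self, refs):
        diff = np.linalg.norm(refs.R_geometry - refs.Rstar_geometry, axis=1)
        assert np.count_nonzero(diff > 1e-12) == 1
        assert diff[8] > 0  # the (n+1) N moved toward C-gamma
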
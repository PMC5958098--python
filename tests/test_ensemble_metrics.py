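import itertools

import numpy as np
import pytest

from prismfold._geometry import rotation_z
from prismfold.ensemble_metrics import (
    TRP_RING6,
    ContactRecord,
    contact_fractions,
    contacts,
    ensemble_rmsd,
    mean_structure,
    nh_pi,
    permuted_backbone_rmsd,
    ring_plane,
    superpose,
    apply_superposition,
)
from prismfold.model_core import Conformer, Ensemble


def _quaternion_grid_rmsd(mobile, target, n=24):
    """Brute-force oracle: best RMSD over a dense rotation grid refined by
    local search (translation handled by centering)."""
    from scipy.spatial.transform import Rotation
    from scipy.optimize import minimize

    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(n):
        res = minimize(rmsd_of, rng.normal(size=3) * 2, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        sup = superpose(X, X)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.matrix, np.eye(3), atol=1e-9)

    def test_recovers_120_degree_rotation(self):
        X = np.random.default_rng(1).normal(size=(12, 3))
        R = rotation_z(120.0)
        sup = superpose(X, X @ R.T)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.matrix, R, atol=1e-8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 3)) * 3
        Y = X @ rotation_z(40.0).T + rng.normal(size=(5, 3)) * 0.3 + 2.0
        sup = superpose(X, Y)
        assert sup.rmsd == pytest.approx(_quaternion_grid_rmsd(X, Y), abs=1e-6)

    def test_proper_rotation_even_for_reflected_target(self):
        X = np.random.default_rng(3).normal(size=(8, 3))
        sup = superpose(X, X * np.array([1, 1, -1]))
        assert np.linalg.det(sup.matrix) == pytest.approx(1.0)

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_rmsd_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 3))
        Y = rng.normal(size=(9, 3))
        base = superpose(X, Y).rmsd
        R = rotation_z(77.0)
        t = np.array([3.0, -2.0, 5.0])
        moved = superpose(X @ R.T + t, Y @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)


def _conf(coords, **kw):
    n = len(coords)
    return Conformer(
        ["A"] * n, list(range(1, n + 1)), ["ALA"] * n, ["CA"] * n,
        ["C"] * n, coords, **kw
    )


class TestMeanStructure:
    def test_identical_members_return_that_model(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        ens = Ensemble([_conf(X), _conf(X.copy()), _conf(X.copy())])
        mean = mean_structure(ens, mask="all")
        assert np.allclose(mean.coords, X, atol=1e-9)
        assert mean.provenance == "unminimized mean structure"

    def test_mirror_displaced_pair_average_to_midpoint(self):
        X = np.random.default_rng(1).normal(size=(6, 3)) * 4
        d = np.zeros_like(X)
        d[0] = [0.3, 0, 0]
        ens = Ensemble([_conf(X + d), _conf(X - d)])
        mean = mean_structure(ens, mask="all")
        sup = superpose(mean.coords, X)
        # midpoint up to the second-order coupling with the rotational fit
        assert sup.rmsd < 0.05 * np.linalg.norm(d[0])
        member_rmsd = superpose(X + d, X).rmsd
        assert sup.rmsd < 0.1 * member_rmsd

    def test_order_independent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3)) * 3
        members = [_conf(X + rng.normal(size=X.shape) * 0.2) for _ in range(5)]
        m1 = mean_structure(Ensemble(members), mask="all")
        m2 = mean_structure(Ensemble(members[::-1]), mask="all")
        assert superpose(m1.coords, m2.coords).rmsd < 1e-5

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            mean_structure(Ensemble([_conf(np.eye(3))]), mask="all")


class TestEnsembleRmsd:
    def test_twenty_copies_give_zero(self):
        X = np.random.default_rng(0).normal(size=(9, 3))
        ens = Ensemble([_conf(X.copy()) for _ in range(20)])
        mean, sd = ensemble_rmsd(ens, mask="all")
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_heavy_at_least_backbone(self, toy_trimer):
        rng = np.random.default_rng(3)
        members = []
        for _ in range(6):
            noise = rng.normal(size=toy_trimer.coords.shape) * 0.3
            # side-chain atoms scatter more than the backbone
            noise[~toy_trimer.backbone_mask] *= 2.5
            members.append(toy_trimer.with_coords(toy_trimer.coords + noise))
        ens = Ensemble(members)
        bb, _ = ensemble_rmsd(ens, mask="backbone")
        heavy, _ = ensemble_rmsd(ens, mask="heavy")
        assert heavy >= bb

    def test_empty_mask_rejected(self, toy_trimer):
        ens = Ensemble([toy_trimer, toy_trimer.copy()])
        with pytest.raises(ValueError):
            ensemble_rmsd(ens, mask=np.zeros(toy_trimer.n_atoms, dtype=bool))


def _pocket_conformer(pair_list):
    """Protein chain A plus a one-atom-per-entry fucose ligand on chain X."""
    chain, resi, resn, name, elem, xyz = [], [], [], [], [], []
    for k, (p_el, l_el, dist) in enumerate(pair_list):
        chain += ["A", "X"]
        resi += [k + 1, 90]
        resn += ["ALA", "FUC"]
        name += [f"{p_el}{k}", f"{l_el}{k}L"]
        elem += [p_el, l_el]
        xyz += [[10.0 * k, 0.0, 0.0], [10.0 * k + dist, 0.0, 0.0]]
    return Conformer(chain, resi, resn, name, elem, xyz)


class TestContacts:
    def test_inclusive_carbon_boundary(self):
        c = _pocket_conformer([("C", "C", 4.5)])
        recs = contacts(c)
        assert len(recs) == 1 and recs[0].type == "hydrophobic"

    def test_no_contact_beyond_cutoffs(self):
        c = _pocket_conformer([("N", "O", 3.6), ("C", "C", 4.51)])
        assert contacts(c) == []

    def test_mixed_pairs_excluded(self):
        c = _pocket_conformer([("C", "O", 3.0)])
        assert contacts(c) == []

    def test_hbond_pair(self):
        c = _pocket_conformer([("O", "O", 3.5), ("N", "O", 3.49)])
        recs = contacts(c)
        assert {r.type for r in recs} == {"hbond"}
        assert len(recs) == 2

    def test_no_ligand_gives_empty(self, toy_trimer):
        assert contacts(toy_trimer) == []

    def test_weight_class_validation(self):
        with pytest.raises(ValueError):
            ContactRecord(("A", 1, "ALA", "CB"), "C1", "hydrophobic", 4.0,
                          0.6, "heavy")


def _fuc_atom(chain, x):
    return dict(chain=chain, x=x)


class TestContactFractions:
    def _ensemble_with_fraction(self, n_members, hits):
        """Ensemble whose single pooled contact appears in `hits` of the
        n_members*3 pockets."""
        members = []
        count = 0
        for m in range(n_members):
            chain, resi, resn, name, elem, xyz = [], [], [], [], [], []
            for p, (pch, lch) in enumerate(zip("ABC", "XYZ")):
                R = rotation_z(120.0 * p)
                base = R @ np.array([5.0, 0.0, 0.0])
                chain.append(pch); resi.append(1); resn.append("ALA")
                name.append("CB"); elem.append("C"); xyz.append(base)
                count += 1
                dist = 4.0 if count <= hits else 6.0
                chain.append(lch); resi.append(90); resn.append("FUC")
                name.append("C1"); elem.append("C")
                xyz.append(base + R @ np.array([dist, 0.0, 0.0]))
            members.append(Conformer(chain, resi, resn, name, elem, xyz))
        return Ensemble(members)

    @pytest.mark.parametrize(
        "hits,frac,wc",
        [(33, 0.55, "bold"), (15, 0.25, "thin"), (6, 0.10, "omitted")],
    )
    def test_fraction_classes_over_60_pockets(self, hits, frac, wc):
        ens = self._ensemble_with_fraction(20, hits)
        recs = contact_fractions(ens)
        assert len(recs) == 1
        assert recs[0].ensemble_fraction == pytest.approx(frac)
        assert recs[0].weight_class == wc

    def test_bold_threshold_nested_in_thin(self):
        for hits in (12, 30, 36, 60):
            recs = contact_fractions(self._ensemble_with_fraction(20, hits))
            for r in recs:
                if r.weight_class == "bold":
                    assert r.ensemble_fraction >= 0.2  # bold implies thin

    def test_symmetric_pockets_pool_to_one_record(self):
        ens = self._ensemble_with_fraction(4, 12)  # every pocket hit
        recs = contact_fractions(ens)
        assert len(recs) == 1
        assert recs[0].ensemble_fraction == 1.0
        assert recs[0].protein_atom[0] == "A"  # canonical frame


def _trp_triad(h_offset=3.0, radius=6.0):
    """Three idealized indole six-rings around the z axis, each with an HE1
    proton placed off the *next* chain's ring plane."""
    ring_local = []
    for k, name in enumerate(TRP_RING6):
        ang = np.deg2rad(60.0 * k)
        ring_local.append([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
    ring_local = np.asarray(ring_local)
    chain, resi, resn, name, elem, xyz = [], [], [], [], [], []
    centers = {}
    for p, ch in enumerate("ABC"):
        R = rotation_z(120.0 * p)
        center = R @ np.array([radius, 0.0, 0.0])
        centers[ch] = center
        for nm, local in zip(TRP_RING6, ring_local):
            chain.append(ch); resi.append(32); resn.append("TRP")
            name.append(nm); elem.append("C")
            xyz.append(center + R @ local)
    for p, ch in enumerate("ABC"):
        nxt = "BCA"[p]
        pos = centers[nxt] + np.array([0.0, 0.0, h_offset])
        chain.append(ch); resi.append(32); resn.append("TRP")
        name.append("HE1"); elem.append("H"); xyz.append(pos)
    return Conformer(chain, resi, resn, name, elem, xyz)


class TestNhPi:
    def test_proton_in_plane_scores_zero(self):
        geoms = nh_pi(_trp_triad(h_offset=0.0), 32)
        assert all(g.h_to_plane == pytest.approx(0.0, abs=1e-9) for g in geoms)

    def test_triad_distances(self):
        geoms = nh_pi(_trp_triad(h_offset=3.0), 32)
        assert len(geoms) == 3
        for g in geoms:
            assert g.h_to_plane == pytest.approx(3.0, abs=1e-9)
            assert g.within_ring_projection

    def test_plane_fit_matches_svd_oracle_on_hexagon(self):
        hexagon = np.array(
            [
                [np.cos(np.deg2rad(60 * k)), np.sin(np.deg2rad(60 * k)), 0.0]
                for k in range(6)
            ]
        )
        R = rotation_z(33.0)
        tilted = hexagon @ R.T + np.array([1.0, 2.0, 3.0])
        _, normal = ring_plane(tilted)
        expect = R @ np.array([0.0, 0.0, 1.0])
        assert min(
            np.linalg.norm(normal - expect), np.linalg.norm(normal + expect)
        ) < 1e-9

    def test_missing_protons_rejected(self):
        c = _trp_triad()
        heavy = c.subset(c.element != "H")
        with pytest.raises(ValueError, match="HE1"):
            nh_pi(heavy, 32)


class TestPermutedRmsd:
    def test_cyclic_relabeling_recovers_zero(self, toy_trimer):
        rotated = toy_trimer.with_coords(toy_trimer.coords @ rotation_z(120.0).T)
        # rotating the whole trimer matches under a cyclic relabeling
        assert permuted_backbone_rmsd(rotated, toy_trimer) < 1e-6

    def test_all_permutations_at_least_as_good(self, toy_trimer):
        rng = np.random.default_rng(0)
        other = toy_trimer.with_coords(
            toy_trimer.coords + rng.normal(size=toy_trimer.coords.shape)
        )
        cyc = permuted_backbone_rmsd(other, toy_trimer, permutations="cyclic")
        full = permuted_backbone_rmsd(other, toy_trimer, permutations="all")
        assert full <= cyc + 1e-12
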
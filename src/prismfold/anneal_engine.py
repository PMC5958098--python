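"""Cartesian restrained simulated annealing under C3 non-crystallographic
symmetry, with the acceptance filter and lowest-energy ensemble selection.

The annealer replaces torsion-angle dynamics with Cartesian Langevin
dynamics over a simplified covalent topology (ideal bond lengths, 1-3
distances standing in for bond angles, a chirality term at each Cα, a
repulsive-only soft-sphere nonbonded term).  What is preserved from the
original protocol is its *acceptance surface*: a trial structure is kept
iff no distance restraint is violated by more than 0.2 Å and no torsion
restraint by more than 2 degrees.  Stage temperatures are control
parameters of the annealer, not physical temperatures; the published
protocols (50,000 K/2,000-step full schedule, 1,000 K/1,000-step reduced
schedule) are expressible as configurations alongside a faster desk-scale
default.

Ambiguous restraints are evaluated with the r^-6 sum-average
(sum_k d_k^-6)^(-1/6) over all candidate chain pairings, so a restraint is
satisfied as soon as *any* symmetry-compatible pairing satisfies it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._geometry import kabsch, reference_geometry
from .model_core import Conformer, Ensemble, SymmetryModel
from .restraint_engine import RestraintSet, symmetrize

__all__ = [
    "KB",
    "AnnealStage",
    "AnnealSchedule",
    "EnergyModel",
    "AcceptanceThresholds",
    "effective_distance",
    "restraint_energy",
    "ncs_energy",
    "Topology",
    "CompiledRestraints",
    "violations",
    "anneal",
    "run_trials",
    "accept",
    "select_ensemble",
]

KB = 1.987204e-3  # kcal mol^-1 K^-1


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealStage:
    t_start: float
    t_end: float
    steps: int
    label: str = ""

    def __post_init__(self):
        if self.t_start <= 0 or self.t_end <= 0:
            raise ValueError("stage temperatures must be positive")
        if self.steps < 0:
            raise ValueError("step count must be non-negative")


@dataclass(frozen=True)
class AnnealSchedule:
    stages: tuple
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        starts = [s.t_start for s in self.stages]
        if any(b > a for a, b in zip(starts, starts[1:])):
            raise ValueError("stage initial temperatures must be non-increasing")

    @classmethod
    def full(cls, seed: int = 0) -> "AnnealSchedule":
        """The full free-trimer protocol: 50,000 K high-temperature stage,
        then two slow-cooling stages (50,000 K and 2,000 K initial)."""
        return cls(
            (
                AnnealStage(50000.0, 50000.0, 2000, "high-temperature annealing"),
                AnnealStage(50000.0, 2000.0, 2000, "first slow cooling"),
                AnnealStage(2000.0, 25.0, 2000, "second slow cooling (Cartesian)"),
            ),
            seed=seed,
        )

    @classmethod
    def reduced(cls, seed: int = 0) -> "AnnealSchedule":
        """The weakened complex protocol: 1,000 K for 1,000 steps per stage."""
        return cls(
            (
                AnnealStage(1000.0, 1000.0, 1000, "annealing"),
                AnnealStage(1000.0, 100.0, 1000, "first cooling"),
                AnnealStage(1000.0, 25.0, 1000, "second cooling (Cartesian)"),
            ),
            seed=seed,
        )

    @classmethod
    def desk(cls, seed: int = 0) -> "AnnealSchedule":
        """Desk-scale default used for synthetic-data work and tests."""
        return cls(
            (
                AnnealStage(3000.0, 3000.0, 300, "high-temperature annealing"),
                AnnealStage(3000.0, 300.0, 400, "first cooling"),
                AnnealStage(300.0, 10.0, 400, "second cooling"),
            ),
            seed=seed,
        )

    @property
    def total_steps(self) -> int:
        return sum(s.steps for s in self.stages)


@dataclass(frozen=True)
class EnergyModel:
    """Force constants of the annealing energy function.

    Units: kcal/mol/Å^2 for distance-like terms, kcal/mol/rad^2 for
    torsions.  ``k_ncs`` defaults to the weak NCS restraint weight of
    10 kcal mol^-1 Å^-2.
    """

    k_noe: float = 30.0
    k_torsion: float = 300.0
    k_ncs: float = 10.0
    k_bond: float = 300.0
    k_angle: float = 100.0
    k_chir: float = 50.0
    k_repulsive: float = 100.0
    # weak harmonic about the well centre: an observed NOE implies real
    # proximity (r^-6 weighting), so distances are gently drawn into the
    # well rather than left anywhere inside it; much smaller than k_noe so
    # it never competes with a genuine bound
    k_center: float = 1.0
    nonbonded: bool = True   # repulsive-only soft sphere
    bonded: bool = True

    def __post_init__(self):
        for name in ("k_noe", "k_torsion", "k_ncs", "k_bond", "k_angle",
                     "k_chir", "k_repulsive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AcceptanceThresholds:
    max_dist_violation: float = 0.2   # Å
    max_torsion_violation: float = 2.0  # degrees

    def __post_init__(self):
        if self.max_dist_violation <= 0 or self.max_torsion_violation <= 0:
            raise ValueError("acceptance thresholds must be strictly positive")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def effective_distance(distances) -> float:
    """r^-6 sum-averaged effective distance (sum_k d_k^-6)^(-1/6)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to average")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def restraint_energy(d_eff: float, lower: float, upper: float, k: float) -> float:
    """Flat-bottom harmonic: zero inside [lower, upper], k*excess^2 outside."""
    if lower > upper:
        raise ValueError(f"lower {lower} > upper {upper}")
    if d_eff > upper:
        return k * (d_eff - upper) ** 2
    if d_eff < lower:
        return k * (lower - d_eff) ** 2
    return 0.0


def _chain_coords(c: Conformer, sym: SymmetryModel):
    chains = sym.chains()
    ref_mask = c.chain_mask(chains[0])
    ref_names = list(zip(c.res_index[ref_mask], c.atom_name[ref_mask]))
    coords = []
    for ch in chains:
        m = c.chain_mask(ch)
        names = list(zip(c.res_index[m], c.atom_name[m]))
        if names != ref_names:
            raise ValueError(f"chain {ch} atom set differs from chain {chains[0]}")
        coords.append(c.coords[m])
    return np.stack(coords)


def ncs_energy(c: Conformer, sym: SymmetryModel, k_ncs: float = 10.0) -> float:
    """Non-crystallographic symmetry energy: k_ncs times the summed squared
    deviation of each chain from the symmetry-averaged chain after optimal
    superposition.  Exactly symmetric conformers score zero."""
    X = _chain_coords(c, sym)
    e, _ = _ncs_energy_grad(X, k_ncs)
    return e


def _ncs_energy_grad(X: np.ndarray, k_ncs: float):
    """(energy, gradient) for chain-stacked coords X of shape (m, n, 3).

    Rotations are treated as constants in the gradient, which is exact at
    the superposition optimum (the standard NCS force approximation)."""
    m = X.shape[0]
    ys = [X[0]]
    rots = [np.eye(3)]
    for ci in range(1, m):
        R, t, _ = kabsch(X[ci], X[0])
        ys.append(X[ci] @ R.T + t)
        rots.append(R)
    Y = np.stack(ys)
    mean = Y.mean(axis=0)
    dev = Y - mean[None]
    e = k_ncs * float(np.sum(dev ** 2))
    grad = np.empty_like(X)
    for ci in range(m):
        grad[ci] = 2.0 * k_ncs * dev[ci] @ rots[ci]
    return e, grad


# ---------------------------------------------------------------------------
# topology and compiled restraints
# ---------------------------------------------------------------------------

# proton radius set so the H-H repulsion floor (2 * 0.8 * 1.15 = 1.84 Å)
# sits above the 1.8 Å van der Waals floor used as the NOE lower bound
_VDW_RADIUS = {"H": 1.15, "C": 1.5, "N": 1.35, "O": 1.3, "S": 1.6}
_REP_SCALE = 0.80

_RESIDUE_BONDS = [
    ("N", "CA"), ("CA", "C"), ("C", "O"),
    ("N", "HN"), ("CA", "HA"), ("CA", "CB"), ("CB", "HB"),
]


class Topology:
    """Covalent topology (bonds, 1-3 pairs, chirality centers, nonbonded
    pair list) for one conformer, with ideal-geometry equilibrium values."""

    def __init__(self, c: Conformer):
        ref = reference_geometry()
        p13 = ref["pairs13"]
        bonds, b0 = [], []
        pairs, p0 = [], []
        chir = []
        from ._geometry import BOND

        lookup = {}
        for i, (ch, r, a) in enumerate(
            zip(c.chain_id, c.res_index, c.atom_name)
        ):
            lookup[(str(ch), int(r), str(a))] = i

        def get(ch, r, a):
            return lookup.get((ch, r, a))

        for ch in c.chains():
            m = c.chain_mask(ch)
            res_ids = sorted(set(c.res_index[m].tolist()))
            for r in res_ids:
                for a, b in _RESIDUE_BONDS:
                    ia, ib = get(ch, r, a), get(ch, r, b)
                    if ia is not None and ib is not None:
                        bonds.append((ia, ib))
                        b0.append(BOND[(a, b)])
                nxt = r + 1
                if get(ch, nxt, "N") is not None:
                    bonds.append((get(ch, r, "C"), get(ch, nxt, "N")))
                    b0.append(BOND[("C", "N+")])
                for (a, b), d0 in p13.items():
                    if b.endswith("+"):
                        ia, ib = get(ch, r, a), get(ch, nxt, b[:-1])
                    else:
                        ia, ib = get(ch, r, a), get(ch, r, b)
                    if ia is not None and ib is not None:
                        pairs.append((ia, ib))
                        p0.append(d0)
                quad = [get(ch, r, n) for n in ("CA", "N", "C", "CB")]
                if all(q is not None for q in quad):
                    chir.append(quad)

        self.bond_i = np.array([b[0] for b in bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in bonds], dtype=int)
        self.bond_d0 = np.array(b0)
        self.pair_i = np.array([p[0] for p in pairs], dtype=int)
        self.pair_j = np.array([p[1] for p in pairs], dtype=int)
        self.pair_d0 = np.array(p0)
        self.chir = np.array(chir, dtype=int).reshape(-1, 4)
        self.chir_v0 = ref["chirality_cb"]

        # nonbonded: all pairs more than three bonds apart in the covalent
        # graph; repulsion floor from scaled van der Waals radii
        n = c.n_atoms
        radii = np.array([_VDW_RADIUS.get(e, 1.5) for e in c.element])
        adj: list[set] = [set() for _ in range(n)]
        for i, j in zip(self.bond_i, self.bond_j):
            adj[i].add(int(j))
            adj[j].add(int(i))
        excluded = np.zeros((n, n), dtype=bool)
        for i in range(n):
            frontier = {i}
            seen = {i}
            for _ in range(3):
                frontier = {k for f in frontier for k in adj[f]} - seen
                seen |= frontier
            for j in seen:
                excluded[i, j] = True
        iu, ju = np.triu_indices(n, k=1)
        keep = ~excluded[iu, ju]
        self.nb_i = iu[keep]
        self.nb_j = ju[keep]
        self.nb_rmin = _REP_SCALE * (radii[self.nb_i] + radii[self.nb_j])
        self.radii = radii
        self.n_atoms = n
        self.excl_code = np.sort(iu[~keep] * n + ju[~keep])


class CompiledRestraints:
    """Distance/torsion restraints resolved to atom-index candidate arrays."""

    def __init__(self, c: Conformer, rset: RestraintSet, sym: SymmetryModel):
        if not rset.symmetrized:
            rset = symmetrize(rset, sym)
        self.rset = rset
        cand_i, cand_j, cand_rid = [], [], []
        lowers, uppers = [], []
        for rid, r in enumerate(rset.distance):
            found = 0
            for pch in r.partner_chains(sym):
                for an_a in r.group_a.atom_names:
                    for an_b in r.group_b.atom_names:
                        try:
                            ia = c.index_of(r.chain_a, r.group_a.res_index, an_a)
                            ib = c.index_of(pch, r.group_b.res_index, an_b)
                        except KeyError:
                            continue
                        if ia == ib:
                            continue
                        cand_i.append(ia)
                        cand_j.append(ib)
                        cand_rid.append(rid)
                        found += 1
            if found == 0:
                raise KeyError(
                    f"restraint {rid}: no atoms found for "
                    f"{r.group_a} - {r.group_b} on chain {r.chain_a}"
                )
            lowers.append(r.lower)
            uppers.append(r.upper)
        self.cand_i = np.array(cand_i, dtype=int)
        self.cand_j = np.array(cand_j, dtype=int)
        self.cand_rid = np.array(cand_rid, dtype=int)
        self.n_dist = len(rset.distance)
        self.lower = np.array(lowers)
        self.upper = np.array(uppers)

        from ._geometry import TORSION_ATOMS

        quads, targets, tols = [], [], []
        for t in rset.torsion:
            spec = TORSION_ATOMS[t.angle_name]
            try:
                quad = [
                    c.index_of(t.chain, t.res_index + off, name)
                    for name, off in spec
                ]
            except KeyError as err:
                raise KeyError(
                    f"torsion {t.angle_name} of residue {t.res_index} "
                    f"chain {t.chain}: {err}"
                ) from None
            quads.append(quad)
            targets.append(np.deg2rad(t.target))
            tols.append(np.deg2rad(t.tolerance))
        self.tors_quad = np.array(quads, dtype=int).reshape(-1, 4)
        self.tors_target = np.array(targets)
        self.tors_tol = np.array(tols)

    # -- evaluation ---------------------------------------------------------

    def distance_violations(self, coords: np.ndarray):
        """Per-restraint effective distances and signed flat-bottom violations."""
        if self.n_dist == 0:
            return np.zeros(0), np.zeros(0)
        diff = coords[self.cand_i] - coords[self.cand_j]
        d = np.maximum(np.linalg.norm(diff, axis=1), 1e-8)
        s = np.bincount(self.cand_rid, weights=d ** -6.0, minlength=self.n_dist)
        d_eff = s ** (-1.0 / 6.0)
        viol = np.maximum(d_eff - self.upper, 0.0) + np.maximum(self.lower - d_eff, 0.0)
        return d_eff, viol

    def torsion_violations_deg(self, coords: np.ndarray):
        if len(self.tors_target) == 0:
            return np.zeros(0)
        phi = _dihedrals(coords, self.tors_quad)
        delta = _wrap_pi(phi - self.tors_target)
        excess = np.maximum(np.abs(delta) - self.tors_tol, 0.0)
        return np.degrees(excess)


def _wrap_pi(x):
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def _dihedrals(coords, quad):
    p0, p1, p2, p3 = (coords[quad[:, k]] for k in range(4))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    p = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", c1, c2)
    y = -np.einsum("ij,ij->i", np.cross(c1, c2), b2) / np.maximum(p, 1e-12)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# full energy function
# ---------------------------------------------------------------------------

class _EnergyFunction:
    """Total energy and gradient over flattened coordinates."""

    def __init__(self, c: Conformer, topo: Topology, comp: CompiledRestraints,
                 model: EnergyModel, sym: SymmetryModel):
        self.topo = topo
        self.comp = comp
        self.model = model
        self.sym = sym
        chains = sym.chains()
        self.chain_index = [np.where(c.chain_id == ch)[0] for ch in chains]
        n_per = {len(ix) for ix in self.chain_index}
        self.ncs_ok = len(n_per) == 1 and len(chains) > 1 and min(n_per) >= 3
        self._nb_cache = None
        self._ncs_rots = None
        self._ncs_tick = 0
        # annealing-time force-constant ramp (restraints and repulsion are
        # soft at high temperature and reach full strength for minimization)
        self.scale_restraint = 1.0
        self.scale_repulsive = 1.0
        # extra torsion attenuation during dynamics: strong torsion wells
        # would stiffen the chains before they can wrap into an assembly
        self.scale_torsion = 1.0
        # boost for the soft-centre term in the final centre-seeking pass
        self.scale_center = 1.0
        # fused harmonic-pair arrays (bonds and 1-3 distances together)
        t = self.topo
        self._harm_i = np.concatenate([t.bond_i, t.pair_i])
        self._harm_j = np.concatenate([t.bond_j, t.pair_j])
        self._harm_d0 = np.concatenate([t.bond_d0, t.pair_d0])
        n_b = len(t.bond_i)
        self._harm_kb_mask = np.zeros(len(self._harm_i), dtype=bool)
        self._harm_kb_mask[:n_b] = True

    def __call__(self, x: np.ndarray):
        coords = x.reshape(-1, 3)
        m = self.model
        e = 0.0
        grad = np.zeros_like(coords)
        terms = {}

        if m.bonded and len(self._harm_i):
            i, j = self._harm_i, self._harm_j
            kvec = np.where(self._harm_kb_mask, m.k_bond, m.k_angle)
            diff = coords[i] - coords[j]
            d = np.maximum(np.sqrt(np.einsum("ij,ij->i", diff, diff)), 1e-8)
            delta = d - self._harm_d0
            coef = (2.0 * kvec * delta / d)[:, None] * diff
            np.add.at(grad, i, coef)
            np.add.at(grad, j, -coef)
            e_harm = kvec * delta ** 2
            terms["bond"] = float(np.sum(e_harm[self._harm_kb_mask]))
            terms["angle"] = float(np.sum(e_harm[~self._harm_kb_mask]))
            terms["chirality"] = self._chirality(coords, grad)
        if m.nonbonded and m.k_repulsive > 0:
            terms["repulsive"] = self._repulsive(coords, grad)
        terms["noe"] = self._distance_restraints(coords, grad)
        terms["torsion"] = self._torsion_restraints(coords, grad)
        if m.k_ncs > 0 and self.ncs_ok:
            X = np.stack([coords[ix] for ix in self.chain_index])
            e_ncs, g_ncs = self._ncs_cached(X, m.k_ncs)
            for ci, ix in enumerate(self.chain_index):
                grad[ix] += g_ncs[ci]
            terms["ncs"] = e_ncs
        e = float(sum(terms.values()))
        self.last_terms = terms
        return e, grad.ravel()

    def _chirality(self, coords, grad):
        t, m = self.topo, self.model
        if len(t.chir) == 0 or m.k_chir == 0:
            return 0.0
        ca, n, c, cb = (coords[t.chir[:, k]] for k in range(4))
        u, v, w = n - ca, c - ca, cb - ca
        uv = np.cross(u, v)
        vol = np.einsum("ij,ij->i", uv, w)
        delta = vol - t.chir_v0
        k = m.k_chir
        coef = 2.0 * k * delta
        g_n = np.cross(v, w) * coef[:, None]
        g_c = np.cross(w, u) * coef[:, None]
        g_cb = uv * coef[:, None]
        np.add.at(grad, t.chir[:, 1], g_n)
        np.add.at(grad, t.chir[:, 2], g_c)
        np.add.at(grad, t.chir[:, 3], g_cb)
        np.add.at(grad, t.chir[:, 0], -(g_n + g_c + g_cb))
        return k * float(np.sum(delta ** 2))

    def _ncs_cached(self, X, k_ncs):
        """NCS energy with superposition rotations refreshed periodically;
        the gradient already treats rotations as constants, so a slightly
        stale rotation changes nothing qualitative."""
        self._ncs_tick += 1
        if self._ncs_rots is None or self._ncs_tick % 8 == 1:
            rots = [np.eye(3)]
            for ci in range(1, X.shape[0]):
                R, _, _ = kabsch(X[ci], X[0])
                rots.append(R)
            self._ncs_rots = rots
        rots = self._ncs_rots
        ys = [X[0] - X[0].mean(axis=0)]
        for ci in range(1, X.shape[0]):
            Xi = X[ci] - X[ci].mean(axis=0)
            ys.append(Xi @ rots[ci].T)
        Y = np.stack(ys)
        mean = Y.mean(axis=0)
        dev = Y - mean[None]
        e = k_ncs * float(np.sum(dev ** 2))
        grad = np.empty_like(X)
        grad[0] = 2.0 * k_ncs * dev[0]
        for ci in range(1, X.shape[0]):
            grad[ci] = 2.0 * k_ncs * dev[ci] @ rots[ci]
        return e, grad

    _NB_SKIN = 1.0

    def _nb_pairs(self, coords):
        """Neighbor-listed repulsion candidates, rebuilt on large moves."""
        t = self.topo
        if self._nb_cache is not None:
            last, pi, pj, rmin = self._nb_cache
            if np.max(np.abs(coords - last)) < 0.5 * self._NB_SKIN / np.sqrt(3):
                return pi, pj, rmin
        from scipy.spatial import cKDTree

        cutoff = float(np.max(t.nb_rmin)) + self._NB_SKIN if len(t.nb_rmin) else 0.0
        pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            code = pairs[:, 0] * t.n_atoms + pairs[:, 1]
            keep = ~np.isin(code, t.excl_code, assume_unique=False)
            pairs = pairs[keep]
        pi = pairs[:, 0] if len(pairs) else np.zeros(0, dtype=int)
        pj = pairs[:, 1] if len(pairs) else np.zeros(0, dtype=int)
        rmin = _REP_SCALE * (t.radii[pi] + t.radii[pj])
        self._nb_cache = (coords.copy(), pi, pj, rmin)
        return pi, pj, rmin

    def _repulsive(self, coords, grad):
        m = self.model
        k = m.k_repulsive * self.scale_repulsive
        pi, pj, rmin = self._nb_pairs(coords)
        if len(pi) == 0 or k == 0:
            return 0.0
        diff = coords[pi] - coords[pj]
        d = np.maximum(np.sqrt(np.einsum("ij,ij->i", diff, diff)), 1e-8)
        pen = rmin - d
        act = pen > 0
        if not np.any(act):
            return 0.0
        pen = pen[act]
        coef = (-2.0 * k * pen / d[act])[:, None] * diff[act]
        np.add.at(grad, pi[act], coef)
        np.add.at(grad, pj[act], -coef)
        return k * float(np.sum(pen ** 2))

    def _distance_restraints(self, coords, grad):
        comp, m = self.comp, self.model
        k_noe = m.k_noe * self.scale_restraint
        if comp.n_dist == 0 or k_noe == 0:
            return 0.0
        diff = coords[comp.cand_i] - coords[comp.cand_j]
        d = np.maximum(np.linalg.norm(diff, axis=1), 1e-8)
        s = np.bincount(comp.cand_rid, weights=d ** -6.0, minlength=comp.n_dist)
        d_eff = s ** (-1.0 / 6.0)
        over = np.maximum(d_eff - comp.upper, 0.0)
        under = np.maximum(comp.lower - d_eff, 0.0)
        e = float(np.sum(k_noe * (over ** 2 + under ** 2)))
        de_ddeff = 2.0 * k_noe * (over - under)
        if m.k_center > 0:
            k_cen = m.k_center * self.scale_restraint * self.scale_center
            center = 0.5 * (comp.lower + comp.upper)
            e += float(np.sum(k_cen * (d_eff - center) ** 2))
            de_ddeff = de_ddeff + 2.0 * k_cen * (d_eff - center)
        # d(d_eff)/d(d_k) = d_eff^7 * d_k^-7
        per_cand = de_ddeff[comp.cand_rid] * (d_eff[comp.cand_rid] ** 7) * d ** -7.0
        coef = (per_cand / d)[:, None] * diff
        np.add.at(grad, comp.cand_i, coef)
        np.add.at(grad, comp.cand_j, -coef)
        return e

    def _torsion_restraints(self, coords, grad):
        comp, m = self.comp, self.model
        k_torsion = m.k_torsion * self.scale_restraint * self.scale_torsion
        nq = len(comp.tors_target)
        if nq == 0 or k_torsion == 0:
            return 0.0
        quad = comp.tors_quad
        p0, p1, p2, p3 = (coords[quad[:, k]] for k in range(4))
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        c1 = np.cross(b1, b2)
        c2 = np.cross(b2, b3)
        p = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
        x = np.einsum("ij,ij->i", c1, c2)
        y = -np.einsum("ij,ij->i", np.cross(c1, c2), b2) / p
        phi = np.arctan2(y, x)
        delta = _wrap_pi(phi - comp.tors_target)
        excess = np.maximum(np.abs(delta) - comp.tors_tol, 0.0)
        e = k_torsion * float(np.sum(excess ** 2))
        dedphi = 2.0 * k_torsion * excess * np.sign(delta)
        act = dedphi != 0
        if np.any(act):
            n1sq = np.maximum(np.einsum("ij,ij->i", c1, c1), 1e-12)
            n2sq = np.maximum(np.einsum("ij,ij->i", c2, c2), 1e-12)
            g0 = (p / n1sq)[:, None] * c1
            g3 = -(p / n2sq)[:, None] * c2
            f12 = (np.einsum("ij,ij->i", b1, b2) / p ** 2)[:, None]
            f32 = (np.einsum("ij,ij->i", b3, b2) / p ** 2)[:, None]
            g1 = -(1.0 + f12) * g0 + f32 * g3
            g2 = f12 * g0 - (1.0 + f32) * g3
            w = dedphi[:, None]
            for k, g in enumerate((g0, g1, g2, g3)):
                np.add.at(grad, quad[act, k], (w * g)[act])
        return e


# ---------------------------------------------------------------------------
# violations, annealing, acceptance, selection
# ---------------------------------------------------------------------------

def violations(c: Conformer, rset: RestraintSet,
               sym: SymmetryModel | None = None):
    """(max distance violation Å, max torsion violation deg, per-restraint
    distance violations) for one conformer."""
    sym = sym or SymmetryModel()
    comp = CompiledRestraints(c, rset, sym)
    _, dviol = comp.distance_violations(c.coords)
    tviol = comp.torsion_violations_deg(c.coords)
    max_d = float(dviol.max()) if dviol.size else 0.0
    max_t = float(tviol.max()) if tviol.size else 0.0
    return max_d, max_t, dviol


_FORCE_CAP = 100.0  # kcal/mol/Å per atom
_DT = 0.02
_FRICTION = 2.0


def anneal(
    start: Conformer,
    restraints: RestraintSet,
    schedule: AnnealSchedule,
    energy: EnergyModel | None = None,
    sym: SymmetryModel | None = None,
    seed: int | None = None,
    minimize_steps: int = 800,
) -> Conformer:
    """Restrained simulated annealing from ``start`` with random initial
    velocities, followed by restrained minimization.

    Deterministic for a fixed seed.  Returns the final conformer annotated
    with its total energy and maximal restraint violations.  Divergent
    dynamics (non-finite or exploding coordinates) raise ``RuntimeError``
    naming the stage.
    """
    energy = energy or EnergyModel()
    sym = sym or SymmetryModel()
    if seed is None:
        seed = schedule.seed
    rng = np.random.default_rng(seed)

    topo = Topology(start)
    comp = CompiledRestraints(start, restraints, sym)
    fn = _EnergyFunction(start, topo, comp, energy, sym)

    x = start.coords.copy()
    n = x.shape[0]
    stages = schedule.stages or ()
    v = rng.normal(
        0.0, np.sqrt(KB * (stages[0].t_start if stages else 300.0)), size=(n, 3)
    )

    def force(xc):
        _, g = fn(xc.ravel())
        f = -g.reshape(-1, 3)
        norms = np.linalg.norm(f, axis=1)
        over = norms > _FORCE_CAP
        if np.any(over):
            f[over] *= (_FORCE_CAP / norms[over])[:, None]
        return f

    total_steps = max(schedule.total_steps, 1)
    steps_done = 0
    f = force(x)
    a = np.exp(-_FRICTION * _DT)
    for stage in stages:
        temps = np.linspace(stage.t_start, stage.t_end, max(stage.steps, 1))
        for step in range(stage.steps):
            # force-constant ramp: soft restraints and repulsion while hot,
            # full strength by the end of the schedule (and in minimization)
            prog = steps_done / total_steps
            fn.scale_restraint = 0.25 + 0.75 * prog
            fn.scale_repulsive = 0.1 + 0.9 * prog
            fn.scale_torsion = 0.2
            steps_done += 1
            t_now = temps[step]
            v += 0.5 * _DT * f
            x += 0.5 * _DT * v
            sigma = np.sqrt(KB * t_now * (1.0 - a * a))
            v = a * v + sigma * rng.standard_normal((n, 3))
            x += 0.5 * _DT * v
            f = force(x)
            v += 0.5 * _DT * f
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e4:
            raise RuntimeError(
                f"dynamics diverged during stage {stage.label!r}"
            )

    fn.scale_restraint = 1.0
    fn.scale_repulsive = 1.0
    fn.scale_torsion = 1.0
    if minimize_steps > 0:
        res = minimize(
            fn, x.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": minimize_steps, "ftol": 1e-12, "gtol": 1e-8},
        )
        x = res.x.reshape(-1, 3)
        # annealed-weight polish: temporarily boosted experimental-term
        # weights push the structure over small barriers toward the
        # feasible basin, then a final pass at the true weights lets any
        # covalent-geometry strain relax before violations are measured.
        # A structure that only *looked* feasible under boosted weights
        # (strain-bought compliance) springs back and is rejected.
        for boost in (8.0, 25.0, 1.0):
            fn.scale_restraint = boost
            res = minimize(
                fn, x.ravel(), jac=True, method="L-BFGS-B",
                options={"maxiter": max(minimize_steps // 2, 100),
                         "ftol": 1e-12, "gtol": 1e-8},
            )
            x = res.x.reshape(-1, 3)
        fn.scale_restraint = 1.0

        # short seeded basin hopping on the violation score: escape
        # slightly-off local minima near the feasible basin; structures
        # with no feasible basin nearby gain nothing and are skipped
        def viol_score(xc):
            _, dv = comp.distance_violations(xc)
            tv = comp.torsion_violations_deg(xc)
            return (float(dv.max()) if dv.size else 0.0) + 0.1 * (
                float(tv.max()) if tv.size else 0.0
            )

        best_x, best_s = x, viol_score(x)
        if 1e-3 < best_s < 0.45:
            for _ in range(6):
                trial_x = best_x + rng.normal(0.0, 0.25, size=best_x.shape)
                fn.scale_restraint = 8.0
                res = minimize(
                    fn, trial_x.ravel(), jac=True, method="L-BFGS-B",
                    options={"maxiter": 150, "ftol": 1e-12, "gtol": 1e-8},
                )
                fn.scale_restraint = 1.0
                res = minimize(
                    fn, res.x, jac=True, method="L-BFGS-B",
                    options={"maxiter": 150, "ftol": 1e-12, "gtol": 1e-8},
                )
                cand = res.x.reshape(-1, 3)
                s = viol_score(cand)
                if s < best_s:
                    best_x, best_s = cand, s
                if best_s < 1e-3:
                    break
        x = best_x

        # centre-seeking pass: pull restrained distances toward their well
        # centres, then relax back to the nearest feasible point.  This
        # walks the structure through the flat interior of the feasible
        # region toward its consensus centre without buying compliance:
        # violations are measured after the final plain relaxation.
        fn.scale_center = 8.0
        res = minimize(
            fn, x.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        fn.scale_center = 1.0
        res = minimize(
            fn, res.x, jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if viol_score(res.x.reshape(-1, 3)) <= best_s + 1e-9:
            x = res.x.reshape(-1, 3)

    e_total, _ = fn(x.ravel())
    _, dviol = comp.distance_violations(x)
    tviol = comp.torsion_violations_deg(x)
    out = start.with_coords(
        x,
        energy=e_total,
        max_dist_violation=float(dviol.max()) if dviol.size else 0.0,
        max_torsion_violation=float(tviol.max()) if tviol.size else 0.0,
        provenance=f"annealed (seed={seed})",
    )
    out.energy_breakdown = dict(fn.last_terms)
    return out


def run_trials(
    start: Conformer,
    restraints: RestraintSet,
    schedule: AnnealSchedule,
    energy: EnergyModel | None = None,
    n_trials: int = 50,
    master_seed: int = 0,
    sym: SymmetryModel | None = None,
) -> list:
    """Seeded annealing trials: trial k runs with seed master_seed + k."""
    out = []
    for k in range(n_trials):
        c = anneal(
            start, restraints, schedule, energy=energy, sym=sym,
            seed=master_seed + k,
        )
        c.model_id = k
        out.append(c)
    return out


def accept(
    c: Conformer,
    restraints: RestraintSet | None = None,
    thresholds: AcceptanceThresholds | None = None,
    sym: SymmetryModel | None = None,
):
    """Acceptance filter: keep iff max distance violation <= 0.2 Å and max
    torsion violation <= 2 degrees (thresholds inclusive).

    Uses the violations recorded on the conformer when present, otherwise
    recomputes them from ``restraints``.  Returns (accepted, report dict).
    """
    thresholds = thresholds or AcceptanceThresholds()
    max_d, max_t = c.max_dist_violation, c.max_torsion_violation
    if max_d is None or max_t is None:
        if restraints is None:
            raise ValueError(
                "conformer carries no violation record and no restraints given"
            )
        max_d, max_t, _ = violations(c, restraints, sym)
    ok = (max_d <= thresholds.max_dist_violation) and (
        max_t <= thresholds.max_torsion_violation
    )
    report = {
        "max_dist_violation": max_d,
        "max_torsion_violation": max_t,
        "dist_threshold": thresholds.max_dist_violation,
        "torsion_threshold": thresholds.max_torsion_violation,
        "accepted": ok,
    }
    return ok, report


def select_ensemble(
    trials,
    n: int = 20,
    thresholds: AcceptanceThresholds | None = None,
) -> Ensemble:
    """Among accepted trial conformers, the n of lowest total energy,
    energy-ascending (stable tie-break by trial order).

    With fewer than n accepted a warning is emitted and all accepted are
    returned; with none accepted the ensemble is empty and its
    selection_note records the no-acceptable-structures outcome.
    """
    thresholds = thresholds or AcceptanceThresholds()
    flagged = [(c.energy, k, c) for k, c in enumerate(trials) if accept(c, thresholds=thresholds)[0]]
    flagged.sort(key=lambda t: (t[0], t[1]))
    chosen = [c for _, _, c in flagged[:n]]
    if not chosen:
        return Ensemble(
            [], selection_note=(
                f"no acceptable structures among {len(trials)} trials"
            ),
        )
    note = (
        f"{len(chosen)} of {len(trials)} trials accepted; "
        f"selected {len(chosen)} lowest-energy"
    )
    if len(chosen) < n:
        warnings.warn(
            f"only {len(chosen)} accepted structures available "
            f"(requested {n})",
            stacklevel=2,
        )
    return Ensemble(chosen, selection_note=note)
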
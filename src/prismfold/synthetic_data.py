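"""Generators for exactly C3-symmetric toy trimers, symmetry-blinded NOE
peak lists, and fast-exchange titration curves.

Two fold templates are provided.  ``beta_prism_surrogate`` is a parametric
idealized strand-swapped prism: each chain contributes three strands to a
ring of nine around the three-fold axis, and the third strand of each chain
pairs with the first strand of the *next* chain, so the closing interface
is genuinely intermolecular — the situation in which intra- and inter-chain
NOEs become indistinguishable.  ``three_helix_bundle_surrogate`` is a
parallel three-helix bundle.  Both are built from ideal peptide geometry,
refined against the covalent energy terms under an exact C3 projection
(only chain A is optimized; B and C are its 120/240-degree rotations), so
the generated model is exactly symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _geometry as geom
from .anneal_engine import EnergyModel, Topology, _EnergyFunction, CompiledRestraints
from .binding_model import TitrationSeries, fraction_bound
from .model_core import Conformer, SymmetryModel
from .restraint_engine import NOEPeak, RestraintSet, TorsionRestraint

__all__ = [
    "ToyTrimerSpec",
    "NoeSimSpec",
    "make_toy_trimer",
    "toy_interfaces",
    "toy_torsion_restraints",
    "extended_trimer",
    "simulate_noes",
    "simulate_titration",
]

FOLDS = ("three_helix_bundle_surrogate", "beta_prism_surrogate")

_STRAND_TORSION = (-139.0, 135.0)
_HELIX_TORSION = (-57.0, -47.0)
_STRAND_RISE = 3.3          # Å per residue along a strand axis
_SHEET_SPACING = 4.9        # Å between adjacent strand axes
_LINKER_LEN = 2


@dataclass(frozen=True)
class ToyTrimerSpec:
    n_res: int = 19
    fold: str = "beta_prism_surrogate"
    seed: int = 0

    def __post_init__(self):
        if self.n_res < 8:
            raise ValueError("need at least 8 residues per chain")
        if self.fold not in FOLDS:
            raise ValueError(f"unknown fold {self.fold!r}; expected one of {FOLDS}")


@dataclass(frozen=True)
class NoeSimSpec:
    cutoff: float = 5.0
    class_edges: tuple = (2.7, 3.6, 5.0)
    false_negative_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        e = tuple(self.class_edges)
        object.__setattr__(self, "class_edges", e)
        if len(e) != 3 or not (0 < e[0] < e[1] < e[2]):
            raise ValueError("class_edges must be three increasing positive values")
        if e[0] > 3.5 or e[1] > 4.5 or e[2] > 6.0:
            raise ValueError(
                "class_edges must stay below the 3.5/4.5/6.0 bound ladder "
                "so every emitted restraint is satisfied by the generator"
            )
        if self.cutoff > e[2]:
            raise ValueError("cutoff must not exceed the outermost class edge")
        if not (0.0 <= self.false_negative_rate <= 1.0):
            raise ValueError("false_negative_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# chain segment builders
# ---------------------------------------------------------------------------

def _segment_arrays(n_res: int, torsion, letters: str):
    torsions = [torsion] * n_res
    res = geom.build_backbone(torsions)
    geom.decorate_backbone(res, torsions, letters)
    return res


def _segment_coords(res: list, letters: str):
    _, _, _, names, _, coords = geom.chain_arrays(res, letters, "A")
    return np.asarray(coords), names


def _align_segment(res: list, letters: str, up: bool):
    """Rigidly align a built segment so its CA axis runs along +z (up) or
    -z (down) and its CA centroid sits at the origin."""
    cas = np.array([r["CA"] for r in res])
    axis = cas[-1] - cas[0]
    if np.linalg.norm(axis) < 1e-6:  # single-residue segment
        axis = res[-1]["C"] - res[0]["N"]
    axis /= np.linalg.norm(axis)
    target = np.array([0.0, 0.0, 1.0 if up else -1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, target))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    centroid = cas.mean(axis=0)
    out = []
    for rd in res:
        out.append({k: R @ (p - centroid) for k, p in rd.items()})
    return out


def _shift(res: list, offset: np.ndarray):
    return [{k: p + offset for k, p in rd.items()} for rd in res]


def _set_strand_phase(res: list, tangent_xy: np.ndarray):
    """Rotate an axis-aligned strand about z so its carbonyl directions
    (which alternate sides along a beta strand) lie along ``tangent_xy``,
    making the local sheet plane tangential to the strand ring and letting
    backbone hydrogen bonds form between ring neighbours."""
    co = []
    for t, rd in enumerate(res):
        v = rd["O"] - rd["C"]
        co.append(((-1.0) ** t) * v)
    m = np.mean(co, axis=0)
    m[2] = 0.0
    norm = np.linalg.norm(m)
    if norm < 1e-9:
        return res
    m /= norm
    t = tangent_xy / np.linalg.norm(tangent_xy)
    ang = np.arctan2(m[0] * t[1] - m[1] * t[0], m[0] * t[0] + m[1] * t[1])
    R = geom.rotation_z(np.degrees(ang))
    return [{k: R @ p for k, p in rd.items()} for rd in res]


def _segment_plan(n_res: int):
    """Residue index ranges (1-based, inclusive) of the three strands."""
    core = n_res - 2 * _LINKER_LEN
    base = core // 3
    extra = core - 3 * base
    lens = [base + (1 if k < extra else 0) for k in range(3)]
    s1 = (1, lens[0])
    s2 = (lens[0] + _LINKER_LEN + 1, lens[0] + _LINKER_LEN + lens[1])
    s3 = (s2[1] + _LINKER_LEN + 1, n_res)
    return s1, s2, s3


def toy_interfaces(n_res: int = 19) -> dict:
    """Strand-interface region pairs of the prism surrogate and their true
    ambiguity labels.  The closing s3-s1 interface is the intermolecular one
    (third strand of each chain pairs with the first strand of the next)."""
    s1, s2, s3 = _segment_plan(n_res)
    return {
        "s1s2": {"regions": (s1, s2), "true_label": "intramolecular"},
        "s2s3": {"regions": (s2, s3), "true_label": "intramolecular"},
        "s3s1": {"regions": (s3, s1), "true_label": "intermolecular"},
    }


def toy_torsion_restraints(n_res: int = 19, tolerance: float = 35.0) -> list:
    """Backbone phi/psi restraints for the strand residues of the prism
    surrogate, centred on the strand template torsions.

    These play the role of experimentally determined torsion restraints in
    the calculation: torsion angles are chirality-sensitive, so they select
    the correct hand of the fold, which distance bounds alone cannot do.
    Returned in chain-slot form.
    """
    out = []
    phi0, psi0 = _STRAND_TORSION
    for lo, hi in _segment_plan(n_res):
        for r in range(lo, hi + 1):
            # only torsions whose four atoms lie within the strand
            if r > lo:
                out.append(TorsionRestraint(r, "phi", phi0, tolerance))
            if r < hi:
                out.append(TorsionRestraint(r, "psi", psi0, tolerance))
    return out


def _toy_letters(n_res: int, fold: str) -> str:
    if fold == "three_helix_bundle_surrogate":
        return "A" * n_res
    strands = _segment_plan(n_res)
    letters = []
    for r in range(1, n_res + 1):
        in_strand = any(lo <= r <= hi for lo, hi in strands)
        letters.append("A" if in_strand else "G")
    return "".join(letters)


def _design_prism_chain(n_res: int):
    """Approximate chain-A design coordinates of the prism surrogate:
    nine strand slots around the three-fold axis at 40-degree spacing,
    chain A contributing the slots at 0, 40 and 80 degrees."""
    s1, s2, s3 = _segment_plan(n_res)
    ring_radius = _SHEET_SPACING / (2.0 * np.sin(np.pi / 9.0))
    letters = _toy_letters(n_res, "beta_prism_surrogate")
    res_out: list = [None] * n_res
    ups = (True, False, True)
    for k, (lo, hi) in enumerate((s1, s2, s3)):
        L = hi - lo + 1
        seg_letters = letters[lo - 1:hi]
        res = _segment_arrays(L, _STRAND_TORSION, seg_letters)
        res = _align_segment(res, seg_letters, up=ups[k])
        angle = np.deg2rad(40.0 * k)
        # carbonyls tangential; the descending strand's pleat parity is
        # flipped so both its sheet interfaces can hydrogen-bond
        phase_sign = -1.0 if not ups[k] else 1.0
        tangent = phase_sign * np.array([-np.sin(angle), np.cos(angle)])
        res = _set_strand_phase(res, tangent)
        z_mid = _STRAND_RISE * (max(hi - lo for lo, hi in (s1, s2, s3))) / 2.0
        offset = np.array(
            [ring_radius * np.cos(angle), ring_radius * np.sin(angle), z_mid]
        )
        res = _shift(res, offset)
        for t, rd in enumerate(res):
            res_out[lo - 1 + t] = rd
    # crude linker placement between strand ends; covalent refinement fixes it
    for lo, hi in ((s1[1] + 1, s2[0] - 1), (s2[1] + 1, s3[0] - 1)):
        a = res_out[lo - 2]["C"]
        b = res_out[hi]["N"]
        n_link = hi - lo + 1
        for t in range(n_link):
            frac = (t + 1) / (n_link + 1)
            p = a + frac * (b - a)
            d = (b - a) / np.linalg.norm(b - a)
            perp = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(d, [1.0, 0.0, 0.0])
            perp /= np.linalg.norm(perp)
            res_out[lo - 1 + t] = {
                "N": p - 1.2 * d,
                "CA": p,
                "C": p + 1.2 * d,
                "O": p + 1.2 * d + 1.2 * perp,
                "HN": p - 1.2 * d + 0.9 * perp,
                "HA": p - 1.0 * perp,
            }
    return res_out, letters


def _design_helix_chain(n_res: int):
    """Chain-A design of the parallel three-helix bundle surrogate."""
    letters = "A" * n_res
    res = _segment_arrays(n_res, _HELIX_TORSION, letters)
    res = _align_segment(res, letters, up=True)
    axis_radius = 5.8
    res = _shift(res, np.array([axis_radius, 0.0, 0.0]))
    return res, letters


def _chain_conformer(res: list, letters: str, chain_id: str = "A") -> Conformer:
    arr = geom.chain_arrays(res, letters, chain_id)
    return Conformer(*arr)


def _replicate_c3(chain_a: Conformer) -> Conformer:
    """Trimer with chains B and C as exact 120/240-degree rotations of A."""
    rots = [geom.rotation_z(0.0), geom.rotation_z(120.0), geom.rotation_z(240.0)]
    ids = ["A", "B", "C"]
    parts = []
    for cid, R in zip(ids, rots):
        parts.append(
            Conformer(
                np.full(chain_a.n_atoms, cid),
                chain_a.res_index,
                chain_a.res_name,
                chain_a.atom_name,
                chain_a.element,
                chain_a.coords @ R.T,
            )
        )
    return Conformer(
        np.concatenate([p.chain_id for p in parts]),
        np.concatenate([p.res_index for p in parts]),
        np.concatenate([p.res_name for p in parts]),
        np.concatenate([p.atom_name for p in parts]),
        np.concatenate([p.element for p in parts]),
        np.concatenate([p.coords for p in parts]),
    )


def _candidate_hbond_wells(trimer: Conformer, detect: float = 3.2):
    """Near-miss backbone HN...O pairs of the design, to be idealized."""
    c = trimer
    hn = np.where(c.atom_name == "HN")[0]
    oo = np.where(c.atom_name == "O")[0]
    wells = []
    for ih in hn:
        best = None
        for io in oo:
            same = c.chain_id[ih] == c.chain_id[io]
            if same and abs(int(c.res_index[ih]) - int(c.res_index[io])) <= 2:
                continue
            d = float(np.linalg.norm(c.coords[ih] - c.coords[io]))
            if d < detect and (best is None or d < best[0]):
                best = (d, io)
        if best is not None:
            wells.append((int(ih), int(best[1]), 1.9, 2.1))
    return wells


def _refine_symmetric(trimer: Conformer, tether_mask: np.ndarray,
                      k_tether: float = 3.0, k_well: float = 50.0,
                      maxiter: int = 600) -> Conformer:
    """Idealize covalent geometry while projecting onto exact C3 symmetry.

    Only chain A coordinates are free; chains B and C are its rotations.
    Strand backbone atoms are weakly tethered to the design so the fold is
    kept, and near-miss backbone hydrogen bonds are pulled into ideal
    geometry so the generated sheets carry identifiable donors."""
    sym = SymmetryModel()
    model = EnergyModel(k_noe=0.0, k_torsion=0.0, k_ncs=0.0)
    topo = Topology(trimer)
    comp = CompiledRestraints(trimer, RestraintSet(symmetrized=True), sym)
    fn = _EnergyFunction(trimer, topo, comp, model, sym)
    n = trimer.n_atoms // 3
    rot_b = geom.rotation_z(120.0)
    rot_c = geom.rotation_z(240.0)
    design_a = trimer.coords[:n].copy()
    tether_a = tether_mask[:n]
    wells = _candidate_hbond_wells(trimer)
    w_i = np.array([w[0] for w in wells], dtype=int)
    w_j = np.array([w[1] for w in wells], dtype=int)
    w_lo = np.array([w[2] for w in wells])
    w_hi = np.array([w[3] for w in wells])

    def full_fn(xa_flat):
        xa = xa_flat.reshape(-1, 3)
        full = np.concatenate([xa, xa @ rot_b.T, xa @ rot_c.T])
        e, g = fn(full.ravel())
        g = g.reshape(-1, 3)
        if len(w_i):
            diff = full[w_i] - full[w_j]
            d = np.maximum(np.linalg.norm(diff, axis=1), 1e-8)
            over = np.maximum(d - w_hi, 0.0)
            under = np.maximum(w_lo - d, 0.0)
            e += k_well * float(np.sum(over ** 2 + under ** 2))
            coef = (2.0 * k_well * (over - under) / d)[:, None] * diff
            np.add.at(g, w_i, coef)
            np.add.at(g, w_j, -coef)
        ga = g[:n] + g[n:2 * n] @ rot_b + g[2 * n:] @ rot_c
        dev = (xa - design_a)[tether_a]
        e += k_tether * float(np.sum(dev ** 2))
        ga[tether_a] += 2.0 * k_tether * (xa - design_a)[tether_a]
        return e, ga.ravel()

    res = minimize(
        full_fn, design_a.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    xa = res.x.reshape(-1, 3)
    full = np.concatenate([xa, xa @ rot_b.T, xa @ rot_c.T])
    return trimer.with_coords(full)


def make_toy_trimer(spec: ToyTrimerSpec) -> Conformer:
    """Build an exactly C3-symmetric toy trimer with protons.

    Pure function of its spec (the seed is recorded for provenance; the
    construction is deterministic)."""
    if spec.fold == "beta_prism_surrogate":
        res, letters = _design_prism_chain(spec.n_res)
    else:
        res, letters = _design_helix_chain(spec.n_res)
    chain_a = _chain_conformer(res, letters)
    trimer = _replicate_c3(chain_a)
    if spec.fold == "beta_prism_surrogate":
        in_strand = np.zeros(trimer.n_atoms, dtype=bool)
        for lo, hi in _segment_plan(spec.n_res):
            in_strand |= (trimer.res_index >= lo) & (trimer.res_index <= hi)
        tether = in_strand & trimer.backbone_mask
    else:
        tether = trimer.backbone_mask.copy()
    out = _refine_symmetric(trimer, tether)
    out.provenance = f"make_toy_trimer({spec.fold}, n_res={spec.n_res}, seed={spec.seed})"
    return out


def extended_trimer(n_res: int, letters: str | None = None) -> Conformer:
    """Extended-chain starting structure: three extended chains arranged
    with exact C3 symmetry well outside the folded radius."""
    letters = letters or _toy_letters(n_res, "beta_prism_surrogate")
    res = _segment_arrays(n_res, (-120.0, 120.0), letters)
    res = _align_segment(res, letters, up=True)
    res = _shift(res, np.array([14.0, 0.0, 0.0]))
    chain_a = _chain_conformer(res, letters)
    return _replicate_c3(chain_a)


# ---------------------------------------------------------------------------
# NOE simulation
# ---------------------------------------------------------------------------

def simulate_noes(c: Conformer, spec: NoeSimSpec) -> list:
    """Symmetry-blinded NOE peaks from a trimer with protons.

    Every proton pair within the cutoff emits a peak recording residue/atom
    identities only (not the chain pairing that produced it); duplicate
    intra/inter peaks merge, keeping the tighter intensity class.  Peaks
    between identical (residue, atom) identities are not observable (they
    fall on the diagonal) and are skipped.  Because every class edge lies
    at or below its distance bound, the generating conformer satisfies all
    emitted restraints exactly.
    """
    h_mask = c.element == "H"
    if not np.any(h_mask):
        raise ValueError("conformer has no protons; NOEs are proton-proton")
    rng = np.random.default_rng(spec.seed)
    chains = c.chains()
    ref = chains[0]
    ref_idx = np.where(h_mask & c.chain_mask(ref))[0]
    all_idx = np.where(h_mask)[0]

    best: dict[tuple, float] = {}
    coords = c.coords
    for ia in ref_idx:
        key_a = (int(c.res_index[ia]), str(c.atom_name[ia]))
        d_all = np.linalg.norm(coords[all_idx] - coords[ia], axis=1)
        close = d_all <= spec.cutoff
        for ib, d in zip(all_idx[close], d_all[close]):
            key_b = (int(c.res_index[ib]), str(c.atom_name[ib]))
            if key_a == key_b:
                continue
            key = tuple(sorted((key_a, key_b)))
            if key not in best or d < best[key]:
                best[key] = float(d)

    e0, e1, e2 = spec.class_edges
    peaks = []
    for key in sorted(best):
        d = best[key]
        if d <= e0:
            cls = "large"
        elif d <= e1:
            cls = "medium"
        else:
            cls = "small"
        if spec.false_negative_rate > 0 and rng.random() < spec.false_negative_rate:
            continue
        peaks.append(NOEPeak(proton_a=key[0], proton_b=key[1], intensity_class=cls))
    return peaks


# ---------------------------------------------------------------------------
# titration simulation
# ---------------------------------------------------------------------------

def simulate_titration(
    k_d: float,
    delta_free: float,
    delta_bound: float,
    p_tot: float,
    ligand_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    resonance_id: str = "sim",
) -> TitrationSeries:
    """Fast-exchange titration curve with additive gaussian noise.

    Deterministic for a fixed seed; ``noise_sd`` is in ppm."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = np.asarray(ligand_grid, dtype=float)
    rng = np.random.default_rng(seed)
    f = fraction_bound(grid, p_tot, k_d)
    delta = delta_free + (delta_bound - delta_free) * np.asarray(f)
    if noise_sd > 0:
        delta = delta + rng.normal(0.0, noise_sd, size=grid.shape)
    return TitrationSeries(
        resonance_id=resonance_id,
        points=tuple(zip(grid.tolist(), np.asarray(delta).tolist())),
        p_tot=p_tot,
    )
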
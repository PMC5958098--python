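"""Superposition, ensemble precision statistics, binding-pocket contact
maps, and NH-pi triad geometry.

Conventions: masks are named atom selections ("backbone" = N, CA, C';
"heavy" = all non-proton atoms).  Ensemble precision is reported as the
mean +/- sd RMSD of the members to the *unminimized mean* structure, the
standard convention for NMR ensembles.  Contact definitions follow the
distance-only rules: C...C pairs at <= 4.5 Å are hydrophobic contacts,
N/O...N/O pairs at <= 3.5 Å are hydrogen bonds (cutoffs inclusive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._geometry import kabsch
from .model_core import Conformer, Ensemble, SymmetryModel

__all__ = [
    "Superposition",
    "ContactRecord",
    "NhPiGeometry",
    "resolve_mask",
    "superpose",
    "apply_superposition",
    "permuted_backbone_rmsd",
    "mean_structure",
    "ensemble_rmsd",
    "contacts",
    "contact_fractions",
    "nh_pi",
]

HYDROPHOBIC_CUTOFF = 4.5  # Å, C...C
HBOND_CUTOFF = 3.5        # Å, N/O...N/O

# six-membered ring of the tryptophan indole
TRP_RING6 = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass(frozen=True)
class Superposition:
    rotation: tuple
    translation: tuple
    rmsd: float

    def __post_init__(self):
        R = np.asarray(self.rotation)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def shift(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)


@dataclass(frozen=True)
class ContactRecord:
    protein_atom: tuple  # (chain, res_index, res_name, atom_name)
    ligand_atom: str
    type: str            # "hydrophobic" | "hbond"
    distance: float
    ensemble_fraction: float | None = None
    weight_class: str | None = None

    def __post_init__(self):
        if self.type not in ("hydrophobic", "hbond"):
            raise ValueError(f"unknown contact type {self.type!r}")
        if self.weight_class not in (None, "bold", "thin", "omitted"):
            raise ValueError(f"unknown weight class {self.weight_class!r}")


@dataclass(frozen=True)
class NhPiGeometry:
    donor: tuple          # (chain, res_index, atom_name)
    acceptor_chain: str
    acceptor_res: int
    h_to_plane: float     # Å
    within_ring_projection: bool

    def __post_init__(self):
        if self.h_to_plane < 0:
            raise ValueError("h_to_plane must be non-negative")


def resolve_mask(c: Conformer, mask) -> np.ndarray:
    """Named or boolean atom selection -> boolean array."""
    if isinstance(mask, str):
        if mask == "backbone":
            return c.backbone_mask
        if mask == "heavy":
            return c.heavy_mask
        if mask == "all":
            return np.ones(c.n_atoms, dtype=bool)
        raise ValueError(f"unknown mask {mask!r}")
    m = np.asarray(mask)
    if m.dtype != bool or m.shape != (c.n_atoms,):
        raise ValueError("mask must be boolean of length n_atoms")
    return m


def superpose(mobile: np.ndarray, target: np.ndarray,
              mask: np.ndarray | None = None) -> Superposition:
    """Least-squares (Kabsch) superposition of mobile onto target.

    ``mask`` selects the atoms used for the fit.  Raises for fewer than
    three atoms or a collinear selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mask is not None:
        mobile = mobile[mask]
        target = target[mask]
    R, t, rmsd = kabsch(mobile, target)
    return Superposition(
        rotation=tuple(map(tuple, R)), translation=tuple(t), rmsd=rmsd
    )


def apply_superposition(coords: np.ndarray, sup: Superposition) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ sup.matrix.T + sup.shift


def permuted_backbone_rmsd(
    a: Conformer,
    b: Conformer,
    sym: SymmetryModel | None = None,
    permutations: str = "cyclic",
) -> float:
    """Backbone RMSD between two trimers, minimized over chain relabelings.

    ``cyclic`` tries the rotations of the chain cycle (the symmetry
    operations); ``all`` tries every bijection, appropriate when comparing
    reconstructions of chemically identical, unlabeled chains.
    """
    sym = sym or SymmetryModel()
    chains = sym.chains()
    bm_a, bm_b = a.backbone_mask, b.backbone_mask
    ref = np.concatenate(
        [np.where((b.chain_id == ch) & bm_b)[0] for ch in chains]
    )
    if permutations == "cyclic":
        perms = [
            tuple(chains[(k + s) % len(chains)] for k in range(len(chains)))
            for s in range(len(chains))
        ]
    elif permutations == "all":
        perms = list(itertools.permutations(chains))
    else:
        raise ValueError("permutations must be 'cyclic' or 'all'")
    best = np.inf
    for perm in perms:
        idx = np.concatenate(
            [np.where((a.chain_id == ch) & bm_a)[0] for ch in perm]
        )
        _, _, r = kabsch(a.coords[idx], b.coords[ref])
        best = min(best, r)
    return float(best)


def mean_structure(e: Ensemble, mask="backbone", tol: float = 1e-6,
                   max_iter: int = 100) -> Conformer:
    """Unminimized mean: iteratively superpose members on the running mean
    (fit on ``mask``) and average until the mean shifts by less than
    ``tol`` Å.  Convergence is independent of member order."""
    if len(e) < 2:
        raise ValueError("need at least 2 ensemble members for a mean structure")
    m = resolve_mask(e[0], mask)
    stack = e.coords_stack()
    mean = stack[0].copy()
    for _ in range(max_iter):
        fitted = []
        for X in stack:
            sup = superpose(X, mean, m)
            fitted.append(apply_superposition(X, sup))
        new_mean = np.mean(fitted, axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    out = e[0].with_coords(mean, provenance="unminimized mean structure")
    out.model_id = 0
    return out


def ensemble_rmsd(e: Ensemble, mask="backbone"):
    """Ensemble precision: per-member RMSD to the unminimized mean after
    superposition on ``mask``; returns (mean, sd) over members in Å."""
    if len(e) < 2:
        raise ValueError("need at least 2 members")
    m = resolve_mask(e[0], mask)
    if not np.any(m):
        raise ValueError("mask selects no atoms")
    ref = mean_structure(e, mask)
    vals = []
    for member in e:
        sup = superpose(member.coords, ref.coords, m)
        moved = apply_superposition(member.coords, sup)
        dev = moved[m] - ref.coords[m]
        vals.append(float(np.sqrt(np.mean(np.sum(dev ** 2, axis=1)))))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std())


def _ligand_mask(c: Conformer, ligand) -> np.ndarray:
    """Ligand selector: residue name (str) or explicit boolean mask."""
    if isinstance(ligand, str):
        return c.res_name == ligand
    return resolve_mask(c, ligand)


def contacts(c: Conformer, ligand="FUC", ligand_chain: str | None = None) -> list:
    """Protein-ligand atom contacts of one conformer.

    Hydrophobic: carbon-carbon pairs at <= 4.5 Å.  Hydrogen bond: N/O-N/O
    pairs at <= 3.5 Å.  Mixed pairs (e.g. C...O) are not contacts.  With no
    ligand present the list is empty.
    """
    lig = _ligand_mask(c, ligand)
    if ligand_chain is not None:
        lig = lig & (c.chain_id == ligand_chain)
    prot = ~_ligand_mask(c, ligand)
    if not np.any(lig):
        return []
    out = []
    lig_idx = np.where(lig)[0]
    prot_idx = np.where(prot)[0]
    for il in lig_idx:
        el = c.element[il]
        d = np.linalg.norm(c.coords[prot_idx] - c.coords[il], axis=1)
        for ip, dist in zip(prot_idx, d):
            ep = c.element[ip]
            if el == "C" and ep == "C" and dist <= HYDROPHOBIC_CUTOFF:
                ctype = "hydrophobic"
            elif el in ("N", "O") and ep in ("N", "O") and dist <= HBOND_CUTOFF:
                ctype = "hbond"
            else:
                continue
            out.append(
                ContactRecord(
                    protein_atom=(
                        str(c.chain_id[ip]), int(c.res_index[ip]),
                        str(c.res_name[ip]), str(c.atom_name[ip]),
                    ),
                    ligand_atom=str(c.atom_name[il]),
                    type=ctype,
                    distance=float(dist),
                )
            )
    return out


def contact_fractions(
    e: Ensemble,
    sym: SymmetryModel | None = None,
    ligand: str = "FUC",
    ligand_chains: tuple = ("X", "Y", "Z"),
) -> list:
    """Pooled contact occurrence over all pockets of the ensemble.

    Each member contributes ``sym.order`` symmetric pockets (one ligand
    copy per pocket, in ``ligand_chains`` order matching successive
    symmetry rotations), so an ensemble of 20 trimers has 60 pockets.
    Protein chains are mapped to a canonical frame per pocket before
    pooling.  Weight classes: fraction >= 0.5 bold, >= 0.2 thin, else
    omitted.
    """
    sym = sym or SymmetryModel()
    chains = sym.chains()
    pockets = 0
    counts: dict[tuple, list] = {}
    for member in e:
        present = [
            lc for lc in ligand_chains
            if np.any((member.res_name == ligand) & (member.chain_id == lc))
        ]
        for p, lc in enumerate(present):
            pockets += 1
            for rec in contacts(member, ligand=ligand, ligand_chain=lc):
                ch, res_i, res_n, at = rec.protein_atom
                offset = (chains.index(ch) - p) % len(chains)
                key = (chains[offset], res_i, res_n, at, rec.ligand_atom, rec.type)
                counts.setdefault(key, []).append(rec.distance)
    out = []
    for key, dists in sorted(counts.items()):
        frac = len(dists) / pockets
        if frac >= 0.5:
            wc = "bold"
        elif frac >= 0.2:
            wc = "thin"
        else:
            wc = "omitted"
        out.append(
            ContactRecord(
                protein_atom=key[0:4],
                ligand_atom=key[4],
                type=key[5],
                distance=float(np.mean(dists)),
                ensemble_fraction=frac,
                weight_class=wc,
            )
        )
    return out


def ring_plane(ring_coords: np.ndarray):
    """Least-squares plane through ring atoms -> (centroid, unit normal)."""
    X = np.asarray(ring_coords, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 ring atoms")
    centroid = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - centroid)
    return centroid, Vt[2]


def nh_pi(c: Conformer, trp_res_index: int,
          sym: SymmetryModel | None = None) -> list:
    """NH-pi geometry of a tryptophan triad at the symmetry core.

    For each chain, the distance from its Trp indole Hε1 proton to the
    least-squares plane of the six-membered indole ring of the cyclically
    next chain's Trp, plus whether the proton's in-plane projection falls
    within the ring.  Requires proton-bearing models (Hε1 present).
    """
    sym = sym or SymmetryModel()
    out = []
    for ch in sym.chains():
        nxt = sym.next_chain(ch)
        try:
            ih = c.index_of(ch, trp_res_index, "HE1")
        except KeyError:
            raise ValueError(
                f"chain {ch} residue {trp_res_index} has no HE1 proton; "
                "NH-pi geometry needs proton-bearing models"
            ) from None
        try:
            ring = np.array(
                [c.coords[c.index_of(nxt, trp_res_index, a)] for a in TRP_RING6]
            )
        except KeyError as err:
            raise ValueError(
                f"chain {nxt} residue {trp_res_index} lacks indole ring atoms: {err}"
            ) from None
        centroid, normal = ring_plane(ring)
        v = c.coords[ih] - centroid
        h = abs(float(np.dot(v, normal)))
        proj = v - np.dot(v, normal) * normal
        ring_radius = float(
            np.max(np.linalg.norm(ring - centroid, axis=1))
        )
        out.append(
            NhPiGeometry(
                donor=(ch, trp_res_index, "HE1"),
                acceptor_chain=nxt,
                acceptor_res=trp_res_index,
                h_to_plane=h,
                within_ring_projection=bool(np.linalg.norm(proj) <= ring_radius),
            )
        )
    return out
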
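"""Domain types shared by all pipeline stages, plus sequence-level utilities.

The central container is :class:`Conformer`, an array-backed collection of
atoms for one model (for trimer work: exactly three chains, A/B/C, each
numbered 1..n per chain).  An :class:`Ensemble` is an ordered list of
conformers sharing one atom set, as in a multi-model NMR deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STANDARD_AA",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "PHOSL_SEQUENCE",
    "PeptideSequence",
    "AtomRecord",
    "Conformer",
    "Ensemble",
    "SymmetryModel",
    "TrimerReport",
    "sequence_mass",
    "validate_trimer",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Average (isotope-abundance weighted) residue masses, Da.  Average rather
# than monoisotopic masses are used throughout because oligomer-size
# bookkeeping is done at the kDa level (gel filtration / MALDI scale).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

WATER_MASS = 18.0153

#: The 40-residue PhoSL lectin monomer (chemically synthesized form).
PHOSL_SEQUENCE = "APVPVTKLVCDGDTYKCTAYLDYGDGKWVAQWDTAVFHTT"


@dataclass(frozen=True)
class PeptideSequence:
    """A one-letter amino-acid sequence restricted to the 20 standard letters."""

    residues: str

    def __post_init__(self) -> None:
        for pos, letter in enumerate(self.residues, start=1):
            if letter not in STANDARD_AA:
                raise ValueError(
                    f"non-standard amino-acid letter {letter!r} at position {pos}"
                )

    @property
    def n(self) -> int:
        return len(self.residues)


def sequence_mass(seq: PeptideSequence | str) -> float:
    """Average molecular mass of a peptide in Da (residue masses + one water).

    Raises ``ValueError`` (naming the offending position) for empty input or
    letters outside the standard 20-letter alphabet.
    """
    if isinstance(seq, PeptideSequence):
        residues = seq.residues
    else:
        residues = seq
    if not residues:
        raise ValueError("empty sequence has no defined mass")
    total = WATER_MASS
    for pos, letter in enumerate(residues, start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[letter]
        except KeyError:
            raise ValueError(
                f"non-standard amino-acid letter {letter!r} at position {pos}"
            ) from None
    return total


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    res_index: int
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


class Conformer:
    """One structural model: parallel per-atom arrays plus coordinates in Å.

    Atom ordering is significant: conformers belonging to one ensemble must
    share an identical ordering so that coordinate arrays are comparable
    index-by-index.
    """

    def __init__(
        self,
        chain_id,
        res_index,
        res_name,
        atom_name,
        element,
        coords,
        model_id: int = 0,
        energy: float | None = None,
        max_dist_violation: float | None = None,
        max_torsion_violation: float | None = None,
        provenance: str | None = None,
    ):
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_index = np.asarray(res_index, dtype=np.int64)
        self.res_name = np.asarray(res_name, dtype="U4")
        self.atom_name = np.asarray(atom_name, dtype="U4")
        self.element = np.asarray(element, dtype="U2")
        self.coords = np.array(coords, dtype=np.float64).reshape(-1, 3)
        n = self.coords.shape[0]
        for arr, label in [
            (self.chain_id, "chain_id"),
            (self.res_index, "res_index"),
            (self.res_name, "res_name"),
            (self.atom_name, "atom_name"),
            (self.element, "element"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"{label} has length {arr.shape}, expected {n}")
        self.model_id = model_id
        self.energy = energy
        self.max_dist_violation = max_dist_violation
        self.max_torsion_violation = max_torsion_violation
        self.provenance = provenance
        self._index: dict[tuple[str, int, str], int] | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms, model_id: int = 0, **kwargs) -> "Conformer":
        atoms = list(atoms)
        return cls(
            [a.chain_id for a in atoms],
            [a.res_index for a in atoms],
            [a.res_name for a in atoms],
            [a.atom_name for a in atoms],
            [a.element for a in atoms],
            [a.xyz for a in atoms],
            model_id=model_id,
            **kwargs,
        )

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                str(self.chain_id[i]),
                int(self.res_index[i]),
                str(self.res_name[i]),
                str(self.atom_name[i]),
                str(self.element[i]),
                tuple(self.coords[i]),
            )
            for i in range(self.n_atoms)
        ]

    # -- basic queries -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(str(c))
        return seen

    def atom_key(self):
        """Identity tuple stream (chain, res_index, res_name, atom_name)."""
        return list(
            zip(
                self.chain_id.tolist(),
                self.res_index.tolist(),
                self.res_name.tolist(),
                self.atom_name.tolist(),
            )
        )

    def index_of(self, chain_id: str, res_index: int, atom_name: str) -> int:
        if self._index is None:
            self._index = {
                (str(c), int(r), str(a)): i
                for i, (c, r, a) in enumerate(
                    zip(self.chain_id, self.res_index, self.atom_name)
                )
            }
        try:
            return self._index[(chain_id, res_index, atom_name)]
        except KeyError:
            raise KeyError(
                f"no atom {atom_name} in residue {res_index} of chain {chain_id}"
            ) from None

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_id == chain_id

    @property
    def backbone_mask(self) -> np.ndarray:
        """Backbone N, Cα, C′ selection."""
        return np.isin(self.atom_name, ("N", "CA", "C"))

    @property
    def heavy_mask(self) -> np.ndarray:
        """All non-proton atoms."""
        return self.element != "H"

    # -- derivation ----------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "Conformer":
        mask = np.asarray(mask)
        return Conformer(
            self.chain_id[mask],
            self.res_index[mask],
            self.res_name[mask],
            self.atom_name[mask],
            self.element[mask],
            self.coords[mask],
            model_id=self.model_id,
            provenance=self.provenance,
        )

    def with_coords(self, coords: np.ndarray, **overrides) -> "Conformer":
        kwargs = dict(
            model_id=self.model_id,
            energy=self.energy,
            max_dist_violation=self.max_dist_violation,
            max_torsion_violation=self.max_torsion_violation,
            provenance=self.provenance,
        )
        kwargs.update(overrides)
        return Conformer(
            self.chain_id,
            self.res_index,
            self.res_name,
            self.atom_name,
            self.element,
            coords,
            **kwargs,
        )

    def copy(self) -> "Conformer":
        return self.with_coords(self.coords.copy())


class Ensemble:
    """Ordered conformer list sharing one atom set (a multi-model deposition)."""

    def __init__(self, members, selection_note: str = ""):
        self.members: list[Conformer] = list(members)
        self.selection_note = selection_note
        if self.members:
            ref = self.members[0].atom_key()
            for k, m in enumerate(self.members[1:], start=1):
                if m.atom_key() != ref:
                    raise ValueError(
                        f"ensemble member {k} has a different atom set than member 0"
                    )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i) -> Conformer:
        return self.members[i]

    def coords_stack(self) -> np.ndarray:
        """(n_members, n_atoms, 3) coordinate array."""
        return np.stack([m.coords for m in self.members])


@dataclass(frozen=True)
class SymmetryModel:
    """Cyclic rotational symmetry: order-n rotation permuting the chains."""

    order: int = 3
    chain_cycle: dict = field(
        default_factory=lambda: {"A": "B", "B": "C", "C": "A"}
    )

    def __post_init__(self) -> None:
        for start in self.chain_cycle:
            c = start
            for _ in range(self.order):
                c = self.chain_cycle[c]
            if c != start:
                raise ValueError(
                    f"chain cycle applied {self.order} times is not the identity"
                )

    def next_chain(self, chain: str) -> str:
        return self.chain_cycle[chain]

    def prev_chain(self, chain: str) -> str:
        inv = {v: k for k, v in self.chain_cycle.items()}
        return inv[chain]

    def chains(self) -> list[str]:
        start = sorted(self.chain_cycle)[0]
        out = [start]
        c = self.chain_cycle[start]
        while c != start:
            out.append(c)
            c = self.chain_cycle[c]
        return out


@dataclass
class TrimerReport:
    chain_count: int
    residues_per_chain: dict
    missing_backbone: list
    flags: list


def validate_trimer(c: Conformer) -> TrimerReport:
    """Report-only sanity check of a trimer model.

    Reports chain count, per-chain residue count and missing backbone atoms
    (N, CA, C per residue); flags a chain count different from three.  Never
    raises.
    """
    chains = c.chains()
    flags: list[str] = []
    if len(chains) != 3:
        flags.append(f"chain count {len(chains)} (expected 3)")
    residues_per_chain: dict[str, int] = {}
    missing: list[tuple[str, int, str]] = []
    for ch in chains:
        mask = c.chain_mask(ch)
        res_ids = sorted(set(c.res_index[mask].tolist()))
        residues_per_chain[ch] = len(res_ids)
        present = set(
            zip(c.res_index[mask].tolist(), c.atom_name[mask].tolist())
        )
        for r in res_ids:
            for name in ("N", "CA", "C"):
                if (r, name) not in present:
                    missing.append((ch, r, name))
                    flags.append(f"chain {ch} residue {r} missing backbone {name}")
    return TrimerReport(
        chain_count=len(chains),
        residues_per_chain=residues_per_chain,
        missing_backbone=missing,
        flags=flags,
    )
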
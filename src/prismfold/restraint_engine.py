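"""Build the symmetric restraint set from NOE peaks, hydrogen-bond donors
and rotamer assignments.

For a symmetric homotrimer, intra- and inter-chain NOE cross-peaks between
the same residue/atom pair are indistinguishable: a peak records residue and
atom identities only.  Restraints are therefore kept in *chain-slot* form
(no concrete chain) until :func:`symmetrize` instantiates each one on all
three chain frames, and ambiguous restraints are later evaluated with the
r^-6 sum-average over every candidate chain pairing.

Distance-bound ladder for NOE intensity classes: large -> 3.5 Å,
medium -> 4.5 Å, small -> 6.0 Å (upper bounds; the lower bound is the
van der Waals contact floor of 1.8 Å throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .model_core import SymmetryModel

__all__ = [
    "NOE_LOWER_BOUND",
    "INTENSITY_BOUNDS",
    "ROTAMER_CENTERS",
    "ProtonGroup",
    "NOEPeak",
    "DistanceRestraint",
    "TorsionRestraint",
    "InterfacePin",
    "RestraintSet",
    "HBondDonor",
    "classify_noe",
    "intensity_to_bound",
    "assign_ambiguity",
    "restraints_from_peaks",
    "symmetrize",
    "hbond_restraints",
    "find_hbond_donors",
    "phosl_interface_pins",
]

NOE_LOWER_BOUND = 1.8  # Å, van der Waals contact floor

INTENSITY_BOUNDS = {"large": 3.5, "medium": 4.5, "small": 6.0}

ROTAMER_CENTERS = (-60.0, 60.0, 180.0)

RANGE_CLASSES = ("intra_residue", "sequential", "medium_range", "long_range")

AMBIGUITY_LABELS = ("intramolecular", "intermolecular", "ambiguous")


@dataclass(frozen=True)
class ProtonGroup:
    """A single proton or an equivalent-proton group on one residue."""

    res_index: int
    atom_names: tuple

    def __post_init__(self):
        if self.res_index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.res_index}")
        if not self.atom_names:
            raise ValueError("empty atom group")
        object.__setattr__(self, "atom_names", tuple(self.atom_names))


@dataclass(frozen=True)
class NOEPeak:
    """An assigned proton-pair cross-peak with an intensity class.

    ``proton_a``/``proton_b`` are (res_index, atom_name) pairs; no chain is
    recorded: symmetry makes intra- and inter-chain peaks indistinguishable.
    """

    proton_a: tuple
    proton_b: tuple
    intensity_class: str

    def __post_init__(self):
        if self.intensity_class not in INTENSITY_BOUNDS:
            raise ValueError(
                f"unknown intensity class {self.intensity_class!r}; "
                f"expected one of {sorted(INTENSITY_BOUNDS)}"
            )

    @property
    def range_class(self) -> str:
        return classify_noe(self)


def classify_noe(peak: NOEPeak) -> str:
    """Sequence-range class from the residue separation |i-j|.

    0 -> intra_residue, 1 -> sequential, 2-4 -> medium_range,
    >4 -> long_range.
    """
    i, j = peak.proton_a[0], peak.proton_b[0]
    if i < 1 or j < 1:
        raise ValueError(f"residue indices must be >= 1, got ({i}, {j})")
    sep = abs(i - j)
    if sep == 0:
        return "intra_residue"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium_range"
    return "long_range"


def intensity_to_bound(intensity_class: str) -> float:
    """Upper distance bound (Å) for an NOE intensity class."""
    try:
        return INTENSITY_BOUNDS[intensity_class]
    except KeyError:
        raise ValueError(
            f"unknown intensity class {intensity_class!r}; "
            f"expected one of {sorted(INTENSITY_BOUNDS)}"
        ) from None


_BACKBONE_PROTONS = ("HN", "HA")


@dataclass(frozen=True)
class InterfacePin:
    """Pin NOEs between two residue regions to one ambiguity label.

    By default only backbone-proton (HN/HA) peaks are pinned — the typical
    interstrand contacts one can assign confidently — while side-chain
    peaks in the same regions keep their sum-averaged ambiguity.
    """

    region_a: tuple
    region_b: tuple
    label: str
    backbone_only: bool = True

    def __post_init__(self):
        if self.label not in ("intramolecular", "intermolecular"):
            raise ValueError(f"pin label must be intra/intermolecular, got {self.label!r}")

    def matches(self, i: int, j: int) -> bool:
        (a0, a1), (b0, b1) = self.region_a, self.region_b
        return (a0 <= i <= a1 and b0 <= j <= b1) or (a0 <= j <= a1 and b0 <= i <= b1)

    def matches_peak(self, peak: "NOEPeak") -> bool:
        if not self.matches(peak.proton_a[0], peak.proton_b[0]):
            return False
        if self.backbone_only:
            return (
                peak.proton_a[1] in _BACKBONE_PROTONS
                and peak.proton_b[1] in _BACKBONE_PROTONS
            )
        return True


def phosl_interface_pins() -> list:
    """The final interface assignment used for the PhoSL trimer calculation:
    the two halves of the kinked strand 1 and the strand 3/strand 4 interface
    are intermolecular; strand 1/2 and strand 2/3 contacts are intramolecular.
    """
    return [
        InterfacePin((27, 31), (34, 39), "intermolecular"),  # beta3 - beta4
        InterfacePin((2, 5), (9, 12), "intermolecular"),     # beta1N - beta1C
        InterfacePin((3, 9), (17, 23), "intramolecular"),    # beta1 - beta2
        InterfacePin((16, 21), (27, 34), "intramolecular"),  # beta2 - beta3
    ]


def assign_ambiguity(peak: NOEPeak, fixed_map=None) -> str:
    """Ambiguity label for one peak under an optional interface pinning.

    Intra-residue and sequential peaks are always intramolecular.  Medium-
    and long-range peaks default to ``ambiguous`` unless their residue pair
    falls in a pinned region pair, in which case the pinned label applies.
    Conflicting pins covering the same peak raise ``ValueError``.
    """
    rc = classify_noe(peak)
    if rc in ("intra_residue", "sequential"):
        return "intramolecular"
    if not fixed_map:
        return "ambiguous"
    i, j = peak.proton_a[0], peak.proton_b[0]
    labels = {pin.label for pin in fixed_map if pin.matches_peak(peak)}
    if len(labels) > 1:
        raise ValueError(
            f"conflicting interface pins for residue pair ({i}, {j}): "
            f"{sorted(labels)}"
        )
    if labels:
        return labels.pop()
    return "ambiguous"


@dataclass(frozen=True)
class DistanceRestraint:
    """A flat-bottom distance restraint between two proton (or heavy-atom)
    groups, in chain-slot form (``chain_a`` is None) or instantiated on a
    concrete chain frame after symmetrization."""

    group_a: ProtonGroup
    group_b: ProtonGroup
    lower: float
    upper: float
    ambiguity: str
    origin: str
    chain_a: str | None = None

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")
        if self.ambiguity not in AMBIGUITY_LABELS:
            raise ValueError(f"unknown ambiguity {self.ambiguity!r}")
        if self.origin not in ("noe", "hbond", "custom"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def range_class(self) -> str:
        sep = abs(self.group_a.res_index - self.group_b.res_index)
        if sep == 0:
            return "intra_residue"
        if sep == 1:
            return "sequential"
        if sep <= 4:
            return "medium_range"
        return "long_range"

    def partner_chains(self, sym: SymmetryModel) -> tuple:
        """Candidate chains for group_b given this restraint's chain frame."""
        if self.chain_a is None:
            raise ValueError("restraint is still in chain-slot form")
        if self.ambiguity == "intramolecular":
            return (self.chain_a,)
        if self.ambiguity == "intermolecular":
            return (sym.next_chain(self.chain_a), sym.prev_chain(self.chain_a))
        return (self.chain_a, sym.next_chain(self.chain_a), sym.prev_chain(self.chain_a))


@dataclass(frozen=True)
class TorsionRestraint:
    """A flat-well torsion restraint (rotamer center ± tolerance)."""

    res_index: int
    angle_name: str
    target: float
    tolerance: float
    chain: str | None = None

    def __post_init__(self):
        if self.angle_name not in ("chi1", "chi2", "phi", "psi"):
            raise ValueError(f"unknown torsion angle {self.angle_name!r}")
        if self.angle_name in ("chi1", "chi2") and self.target not in ROTAMER_CENTERS:
            raise ValueError(
                f"{self.angle_name} target must be a rotamer center "
                f"{ROTAMER_CENTERS}, got {self.target}"
            )
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class RestraintSet:
    """Distance and torsion restraints plus Table-1-style bookkeeping."""

    distance: list = field(default_factory=list)
    torsion: list = field(default_factory=list)
    symmetrized: bool = False

    @property
    def counts_by_category(self) -> dict:
        counts: dict[str, int] = {}
        for rc in ("sequential", "medium_range", "long_range"):
            for amb in AMBIGUITY_LABELS:
                counts[f"{rc}:{amb}"] = 0
        counts["intra_residue"] = 0
        counts["hbond"] = 0
        counts["custom"] = 0
        for r in self.distance:
            if r.origin == "hbond":
                counts["hbond"] += 1
            elif r.origin == "custom":
                counts["custom"] += 1
            elif r.range_class == "intra_residue":
                counts["intra_residue"] += 1
            else:
                counts[f"{r.range_class}:{r.ambiguity}"] += 1
        counts["torsion:chi1"] = sum(1 for t in self.torsion if t.angle_name == "chi1")
        counts["torsion:chi2"] = sum(1 for t in self.torsion if t.angle_name == "chi2")
        counts["torsion:other"] = sum(
            1 for t in self.torsion if t.angle_name not in ("chi1", "chi2")
        )
        counts["total_distance"] = len(self.distance)
        counts["total_torsion"] = len(self.torsion)
        return counts


def restraints_from_peaks(
    peaks, fixed_map=None, lower: float = NOE_LOWER_BOUND
) -> list:
    """NOE peaks -> chain-slot distance restraints (class ladder bounds)."""
    out = []
    for p in peaks:
        out.append(
            DistanceRestraint(
                group_a=ProtonGroup(p.proton_a[0], _as_names(p.proton_a[1])),
                group_b=ProtonGroup(p.proton_b[0], _as_names(p.proton_b[1])),
                lower=lower,
                upper=intensity_to_bound(p.intensity_class),
                ambiguity=assign_ambiguity(p, fixed_map),
                origin="noe",
            )
        )
    return out


def _as_names(name) -> tuple:
    if isinstance(name, str):
        return (name,)
    return tuple(name)


def symmetrize(rset: RestraintSet, sym: SymmetryModel) -> RestraintSet:
    """Instantiate every unique restraint on all chain frames (count x order).

    Idempotent: a set already flagged as symmetrized is returned unchanged.
    """
    if rset.symmetrized:
        return rset
    chains = sym.chains()
    distance = [replace(r, chain_a=ch) for r in rset.distance for ch in chains]
    torsion = [replace(t, chain=ch) for t in rset.torsion for ch in chains]
    return RestraintSet(distance=distance, torsion=torsion, symmetrized=True)


@dataclass(frozen=True)
class HBondDonor:
    """A hydrogen-bond donor with an (optionally unknown) acceptor."""

    res_donor: int
    donor_atom: str
    h_atom: str
    res_acceptor: int | None = None
    acceptor_atom: str | None = None
    ambiguity: str = "intramolecular"


# Conventional NMR hydrogen-bond bounds (Å): proton-acceptor and
# donor-heavy-atom-acceptor.
HBOND_H_BOUNDS = (1.8, 2.3)
HBOND_HEAVY_BOUNDS = (2.8, 3.3)


def hbond_restraints(donors) -> list:
    """Two distance restraints per identified hydrogen bond, per monomer.

    H -> acceptor at 1.8-2.3 Å and donor heavy atom -> acceptor at
    2.8-3.3 Å.  Donors whose acceptor has not been determined are skipped
    with a warning.  Returned in chain-slot form; symmetrization then
    triples the count (e.g. 20 donors -> 40 -> 120 for the trimer).
    """
    out = []
    for d in donors:
        if d.res_acceptor is None or d.acceptor_atom is None:
            warnings.warn(
                f"donor {d.donor_atom}/{d.res_donor} has no determined acceptor; skipped",
                stacklevel=2,
            )
            continue
        acc = ProtonGroup(d.res_acceptor, (d.acceptor_atom,))
        out.append(
            DistanceRestraint(
                ProtonGroup(d.res_donor, (d.h_atom,)), acc,
                *HBOND_H_BOUNDS, ambiguity=d.ambiguity, origin="hbond",
            )
        )
        out.append(
            DistanceRestraint(
                ProtonGroup(d.res_donor, (d.donor_atom,)), acc,
                *HBOND_HEAVY_BOUNDS, ambiguity=d.ambiguity, origin="hbond",
            )
        )
    return out


def find_hbond_donors(c, sym: SymmetryModel | None = None) -> list:
    """Identify backbone amide hydrogen bonds from a calculated structure.

    Mirrors the protocol of determining acceptors from the calculated
    structure: a chain-A amide proton HN donates to a carbonyl oxygen if
    the proton-acceptor and nitrogen-acceptor distances both fall inside
    the restraint windows (1.8-2.3 Å and 2.8-3.3 Å).  The ambiguity label
    records whether the acceptor lies on the same chain.  Returned per
    monomer (chain-slot form); symmetrization replicates across chains.
    """
    import numpy as np

    sym = sym or SymmetryModel()
    ref = sym.chains()[0]
    h_idx = [
        k for k in range(c.n_atoms)
        if c.chain_id[k] == ref and c.atom_name[k] == "HN"
    ]
    o_idx = [k for k in range(c.n_atoms) if c.atom_name[k] == "O"]
    donors = []
    for ih in h_idx:
        res_d = int(c.res_index[ih])
        try:
            i_n = c.index_of(ref, res_d, "N")
        except KeyError:
            continue
        best = None
        for io in o_idx:
            if io == ih:
                continue
            d_ho = float(np.linalg.norm(c.coords[ih] - c.coords[io]))
            d_no = float(np.linalg.norm(c.coords[i_n] - c.coords[io]))
            if not (HBOND_H_BOUNDS[0] <= d_ho <= HBOND_H_BOUNDS[1]):
                continue
            if not (HBOND_HEAVY_BOUNDS[0] <= d_no <= HBOND_HEAVY_BOUNDS[1]):
                continue
            if best is None or d_ho < best[0]:
                best = (d_ho, io)
        if best is None:
            continue
        io = best[1]
        label = (
            "intramolecular" if c.chain_id[io] == ref else "intermolecular"
        )
        donors.append(
            HBondDonor(
                res_donor=res_d,
                donor_atom="N",
                h_atom="HN",
                res_acceptor=int(c.res_index[io]),
                acceptor_atom="O",
                ambiguity=label,
            )
        )
    return donors
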
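import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prismfold.model_core import SymmetryModel
from prismfold.restraint_engine import (
    DistanceRestraint,
    HBondDonor,
    InterfacePin,
    NOEPeak,
    ProtonGroup,
    RestraintSet,
    assign_ambiguity,
    classify_noe,
    find_hbond_donors,
    hbond_restraints,
    intensity_to_bound,
    phosl_interface_pins,
    restraints_from_peaks,
    symmetrize,
)


def peak(i, j, cls="medium"):
    return NOEPeak((i, "HA"), (j, "HN"), cls)


class TestClassify:
    @pytest.mark.parametrize(
        "i,j,expect",
        [
            (5, 5, "intra_residue"),
            (5, 6, "sequential"),
            (6, 5, "sequential"),
            (5, 7, "medium_range"),
            (5, 8, "medium_range"),
            (5, 9, "medium_range"),
            (5, 12, "long_range"),
        ],
    )
    def test_range_classes(self, i, j, expect):
        assert classify_noe(peak(i, j)) == expect

    def test_invalid_residue_index(self):
        with pytest.raises(ValueError):
            classify_noe(NOEPeak((-1, "HA"), (3, "HN"), "large"))


class TestBounds:
    @pytest.mark.parametrize(
        "cls,bound", [("large", 3.5), ("medium", 4.5), ("small", 6.0)]
    )
    def test_class_ladder(self, cls, bound):
        assert intensity_to_bound(cls) == bound

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            intensity_to_bound("huge")


class TestAmbiguity:
    def test_sequential_always_intramolecular(self):
        pins = [InterfacePin((1, 10), (1, 10), "intermolecular")]
        assert assign_ambiguity(peak(5, 6), pins) == "intramolecular"

    def test_pinned_interface(self):
        # the strand3-strand4 interface of the lectin: intermolecular
        p = NOEPeak((29, "HN"), (37, "HN"), "large")
        assert assign_ambiguity(p, phosl_interface_pins()) == "intermolecular"

    def test_default_is_ambiguous(self):
        assert assign_ambiguity(peak(2, 19)) == "ambiguous"
        assert assign_ambiguity(peak(2, 19), phosl_interface_pins()) == "ambiguous"

    def test_conflicting_pins_rejected(self):
        pins = [
            InterfacePin((1, 5), (8, 12), "intermolecular"),
            InterfacePin((2, 6), (8, 12), "intramolecular"),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            assign_ambiguity(peak(3, 9), pins)

    @given(
        i=st.integers(min_value=1, max_value=40),
        j=st.integers(min_value=1, max_value=40),
    )
    @settings(max_examples=100, deadline=None)
    def test_sequential_never_relabelled(self, i, j):
        if abs(i - j) > 1:
            return
        p = peak(i, j)
        assert assign_ambiguity(p, phosl_interface_pins()) == "intramolecular"


class TestSymmetrize:
    def test_count_triples(self, sym):
        rset = RestraintSet(distance=restraints_from_peaks([peak(1, 9)]))
        out = symmetrize(rset, sym)
        assert len(out.distance) == 3
        assert {r.chain_a for r in out.distance} == {"A", "B", "C"}

    def test_202_sequential_peaks_give_606(self, sym):
        # Table-1-style bookkeeping: each NOE is three constraints
        peaks = [peak(i % 30 + 1, i % 30 + 2, "large") for i in range(202)]
        out = symmetrize(RestraintSet(distance=restraints_from_peaks(peaks)), sym)
        assert len(out.distance) == 606

    def test_empty_set(self, sym):
        out = symmetrize(RestraintSet(), sym)
        assert out.distance == [] and out.torsion == []

    def test_idempotent(self, sym):
        rset = symmetrize(
            RestraintSet(distance=restraints_from_peaks([peak(1, 9)])), sym
        )
        again = symmetrize(rset, sym)
        assert again is rset

    @given(n=st.integers(min_value=0, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_counting_identity(self, n, sym):
        # total distance constraints = 3*(unique NOEs) + 3*(h-bond rows)
        peaks = [peak(k % 17 + 1, (3 * k) % 17 + 2) for k in range(n)]
        peaks = list(dict.fromkeys((p.proton_a, p.proton_b, p.intensity_class) for p in peaks))
        peaks = [NOEPeak(*t) for t in peaks]
        donors = [HBondDonor(2, "N", "HN", 9, "O")]
        rset = RestraintSet(
            distance=restraints_from_peaks(peaks) + hbond_restraints(donors)
        )
        out = symmetrize(rset, sym)
        assert len(out.distance) == 3 * len(peaks) + 3 * 2


class TestHBonds:
    def test_twenty_donors_give_120_for_trimer(self, sym):
        donors = [
            HBondDonor(i, "N", "HN", i + 4, "O") for i in range(1, 21)
        ]
        per_monomer = hbond_restraints(donors)
        assert len(per_monomer) == 40  # two constraints per bond
        out = symmetrize(RestraintSet(distance=per_monomer), sym)
        assert len(out.distance) == 120
        assert out.counts_by_category["hbond"] == 120

    def test_bounds_convention(self):
        r_h, r_heavy = hbond_restraints([HBondDonor(2, "N", "HN", 9, "O")])
        assert (r_h.lower, r_h.upper) == (1.8, 2.3)
        assert (r_heavy.lower, r_heavy.upper) == (2.8, 3.3)

    def test_no_donors(self):
        assert hbond_restraints([]) == []

    def test_missing_acceptor_skipped_with_warning(self):
        donors = [HBondDonor(2, "N", "HN"), HBondDonor(3, "N", "HN", 9, "O")]
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = hbond_restraints(donors)
        assert len(out) == 2
        assert any("no determined acceptor" in str(w.message) for w in rec)

    def test_structure_based_donors_fit_windows(self, toy_trimer, sym):
        import numpy as np

        donors = find_hbond_donors(toy_trimer, sym)
        assert len(donors) >= 8  # sheets of the prism surrogate carry H-bonds
        for d in donors:
            ih = toy_trimer.index_of("A", d.res_donor, d.h_atom)
            ch_acc = "A" if d.ambiguity == "intramolecular" else None
            # acceptor distance fits the restraint window on some chain
            dists = []
            for ch in ("A", "B", "C"):
                if ch_acc and ch != ch_acc:
                    continue
                io = toy_trimer.index_of(ch, d.res_acceptor, d.acceptor_atom)
                dists.append(np.linalg.norm(toy_trimer.coords[ih] - toy_trimer.coords[io]))
            assert min(dists) == pytest.approx(2.05, abs=0.26)


class TestValidation:
    def test_lower_above_upper_rejected(self):
        with pytest.raises(ValueError):
            DistanceRestraint(
                ProtonGroup(1, ("HA",)), ProtonGroup(2, ("HN",)),
                5.0, 3.5, "ambiguous", "noe",
            )

    def test_chi_rotamer_centers_enforced(self):
        from prismfold.restraint_engine import TorsionRestraint

        with pytest.raises(ValueError):
            TorsionRestraint(3, "chi1", -55.0, 10.0)
        TorsionRestraint(3, "chi1", -60.0, 10.0)
        TorsionRestraint(3, "phi", -139.0, 30.0)  # backbone targets are free
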
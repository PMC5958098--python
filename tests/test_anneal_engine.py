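import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prismfold.anneal_engine import (
    AcceptanceThresholds,
    AnnealSchedule,
    AnnealStage,
    CompiledRestraints,
    EnergyModel,
    Topology,
    _EnergyFunction,
    accept,
    anneal,
    effective_distance,
    ncs_energy,
    restraint_energy,
    select_ensemble,
    violations,
)
from prismfold.model_core import Conformer, SymmetryModel
from prismfold.restraint_engine import (
    DistanceRestraint,
    ProtonGroup,
    RestraintSet,
    TorsionRestraint,
    symmetrize,
)
from prismfold.synthetic_data import extended_trimer


class TestEffectiveDistance:
    def test_single_contributor_is_identity(self):
        assert effective_distance([4.0]) == pytest.approx(4.0)

    def test_two_equal_contributors_closed_form(self):
        # (2 * d^-6)^(-1/6) = d * 2^(-1/6)
        assert effective_distance([4.0, 4.0]) == pytest.approx(
            4.0 * 2 ** (-1 / 6), abs=1e-12
        )

    def test_far_contributor_negligible(self):
        assert effective_distance([3.0, 100.0]) == pytest.approx(3.0, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            effective_distance([3.0, 0.0])
        with pytest.raises(ValueError):
            effective_distance([])

    @given(
        ds=st.lists(
            st.floats(min_value=0.5, max_value=50.0), min_size=1, max_size=8
        ),
        extra=st.floats(min_value=0.5, max_value=50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_minimum_and_monotone(self, ds, extra):
        d_eff = effective_distance(ds)
        assert d_eff <= min(ds) + 1e-9
        if len(ds) == 1:
            assert d_eff == pytest.approx(ds[0])
        # adding a contributor never increases the effective distance
        assert effective_distance(ds + [extra]) <= d_eff + 1e-9


class TestRestraintEnergy:
    def test_inside_well_is_zero(self):
        assert restraint_energy(4.0, 1.8, 4.5, 1.0) == 0.0

    def test_harmonic_above(self):
        assert restraint_energy(5.0, 1.8, 4.5, 1.0) == pytest.approx(0.25)

    def test_harmonic_below(self):
        assert restraint_energy(1.5, 1.8, 4.5, 2.0) == pytest.approx(2 * 0.09)

    def test_gradient_continuous_at_upper(self):
        h = 1e-6
        k = 3.0
        up = (restraint_energy(4.5 + h, 1.8, 4.5, k) - restraint_energy(4.5, 1.8, 4.5, k)) / h
        down = (restraint_energy(4.5, 1.8, 4.5, k) - restraint_energy(4.5 - h, 1.8, 4.5, k)) / h
        assert up == pytest.approx(0.0, abs=1e-4)
        assert down == pytest.approx(0.0, abs=1e-4)


class TestNcsEnergy:
    def test_exact_symmetry_scores_zero(self, toy_trimer, sym):
        assert ncs_energy(toy_trimer, sym, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_zero_force_constant(self, toy_trimer, sym):
        assert ncs_energy(toy_trimer, sym, 0.0) == 0.0

    def test_internal_distortion_scores_positive(self, toy_trimer, sym):
        c = toy_trimer.copy()
        i = c.index_of("A", 3, "CA")
        c.coords[i] += np.array([1.0, 0.0, 0.0])
        assert ncs_energy(c, sym, 10.0) > 1.0

    def test_rigid_motion_of_a_chain_is_free(self, toy_trimer, sym):
        # superposition removes rigid-body differences between chains
        c = toy_trimer.copy()
        c.coords[c.chain_mask("B")] += np.array([1.0, 0.0, 0.0])
        assert ncs_energy(c, sym, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_chain_mismatch_rejected(self, toy_trimer, sym):
        broken = toy_trimer.subset(
            ~((toy_trimer.chain_id == "C") & (toy_trimer.res_index == 1))
        )
        with pytest.raises(ValueError, match="differs"):
            ncs_energy(broken, sym, 10.0)


class TestEnergyGradients:
    def test_total_gradient_matches_finite_differences(self, small_trimer, sym):
        rset = symmetrize(
            RestraintSet(
                distance=[
                    DistanceRestraint(
                        ProtonGroup(2, ("HA",)), ProtonGroup(9, ("HN",)),
                        1.8, 4.5, "ambiguous", "noe",
                    )
                ],
                torsion=[TorsionRestraint(3, "phi", -139.0, 5.0)],
            ),
            sym,
        )
        topo = Topology(small_trimer)
        comp = CompiledRestraints(small_trimer, rset, sym)
        fn = _EnergyFunction(small_trimer, topo, comp, EnergyModel(), sym)
        rng = np.random.default_rng(0)
        x0 = small_trimer.coords.ravel() + rng.normal(
            size=small_trimer.coords.size
        ) * 0.3
        _, g = fn(x0)
        for _ in range(3):
            d = rng.normal(size=x0.shape)
            d /= np.linalg.norm(d)
            h = 1e-6
            e1, _ = fn(x0 + h * d)
            e2, _ = fn(x0 - h * d)
            fd = (e1 - e2) / (2 * h)
            assert fd == pytest.approx(float(np.dot(g, d)), rel=1e-4, abs=1e-5)


def _annotated(energy, max_d, max_t, model_id=0):
    c = Conformer(
        ["A", "A", "A"], [1, 1, 1], ["ALA"] * 3, ["N", "CA", "C"],
        ["N", "C", "C"], np.eye(3),
        model_id=model_id, energy=energy,
        max_dist_violation=max_d, max_torsion_violation=max_t,
    )
    return c


class TestAccept:
    @pytest.mark.parametrize(
        "dv,tv,expect",
        [
            (0.19, 1.9, True),
            (0.2, 2.0, True),    # thresholds are inclusive
            (0.21, 0.0, False),
            (0.0, 2.5, False),
        ],
    )
    def test_boundary_behavior(self, dv, tv, expect):
        ok, report = accept(_annotated(0.0, dv, tv))
        assert ok is expect
        assert report["accepted"] is expect

    @given(
        dv=st.floats(min_value=0, max_value=1),
        tv=st.floats(min_value=0, max_value=5),
        loosen_d=st.floats(min_value=0, max_value=1),
        loosen_t=st.floats(min_value=0, max_value=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_thresholds(self, dv, tv, loosen_d, loosen_t):
        tight = AcceptanceThresholds(0.2, 2.0)
        loose = AcceptanceThresholds(0.2 + loosen_d, 2.0 + loosen_t)
        c = _annotated(0.0, dv, tv)
        if accept(c, thresholds=tight)[0]:
            assert accept(c, thresholds=loose)[0]


class TestSelectEnsemble:
    def test_selects_lowest_energy(self):
        trials = [_annotated(float(10 - k), 0.0, 0.0, model_id=k) for k in range(30)]
        ens = select_ensemble(trials, n=20)
        assert len(ens) == 20
        energies = [c.energy for c in ens]
        assert energies == sorted(energies)
        assert max(energies) < 10 - 9  # the ten highest energies dropped

    def test_shortage_returns_all_accepted_with_warning(self):
        trials = [_annotated(1.0, 0.0, 0.0)] * 8 + [_annotated(0.0, 0.5, 0.0)] * 42
        with pytest.warns(UserWarning, match="only 8"):
            ens = select_ensemble(trials, n=20)
        assert len(ens) == 8

    def test_zero_accepted_gives_empty_with_status(self):
        trials = [_annotated(0.0, 0.5, 0.0)] * 5
        ens = select_ensemble(trials, n=20)
        assert len(ens) == 0
        assert "no acceptable structures" in ens.selection_note

    def test_ties_broken_by_trial_order(self):
        trials = [_annotated(1.0, 0.0, 0.0, model_id=k) for k in range(5)]
        ens = select_ensemble(trials, n=2)
        assert [c.model_id for c in ens] == [0, 1]


class TestSchedule:
    def test_published_protocols_expressible(self):
        full = AnnealSchedule.full()
        assert full.stages[0].t_start == 50000.0
        assert full.stages[0].steps == 2000
        reduced = AnnealSchedule.reduced()
        assert all(s.t_start == 1000.0 for s in reduced.stages)
        assert all(s.steps == 1000 for s in reduced.stages)

    def test_increasing_stage_temperatures_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(
                (AnnealStage(1000, 100, 10), AnnealStage(2000, 100, 10))
            )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            AnnealStage(0.0, 100, 10)


_SHORT = AnnealSchedule(
    (AnnealStage(500.0, 500.0, 60, "hot"), AnnealStage(500.0, 10.0, 120, "cool"))
)


class TestAnneal:
    def test_deterministic_for_fixed_seed(self, small_trimer, toy_trimer, sym):
        start = extended_trimer(16)
        rset = symmetrize(
            RestraintSet(
                distance=[
                    DistanceRestraint(
                        ProtonGroup(2, ("HA",)), ProtonGroup(12, ("HA",)),
                        1.8, 6.0, "ambiguous", "noe",
                    )
                ]
            ),
            sym,
        )
        a = anneal(start, rset, _SHORT, seed=7, minimize_steps=50)
        b = anneal(start, rset, _SHORT, seed=7, minimize_steps=50)
        assert np.array_equal(a.coords, b.coords)
        c = anneal(start, rset, _SHORT, seed=8, minimize_steps=50)
        assert not np.array_equal(a.coords, c.coords)

    def test_empty_restraints_runs_with_zero_restraint_energy(self, sym):
        start = extended_trimer(10)
        out = anneal(
            start, symmetrize(RestraintSet(), sym), _SHORT, seed=0,
            minimize_steps=50,
        )
        assert out.max_dist_violation == 0.0
        assert out.max_torsion_violation == 0.0
        assert out.energy_breakdown["noe"] == 0.0

    def test_truth_satisfies_its_own_restraints(self, toy_trimer, toy_restraints, sym):
        # conservation check for the whole restraint pipeline
        max_d, max_t, _ = violations(toy_trimer, toy_restraints, sym)
        assert max_d == pytest.approx(0.0, abs=1e-9)
        assert max_t == pytest.approx(0.0, abs=1e-9)
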
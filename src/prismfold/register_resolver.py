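"""Systematic resolution of interface register: decide per strand
interface whether its NOEs are intra- or intermolecular by running
annealing trials under each hypothesis and comparing acceptance counts.

This reproduces the logic of the original determination: with the closing
interface forced intramolecular no acceptable structure emerges, while the
intermolecular alternative yields accepted structures, so the contacts
must be intermolecular; remaining interfaces are then fixed accordingly.
The decision statistic is the acceptance-count comparison, not the
absolute counts (trial budgets are configurable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .anneal_engine import (
    AcceptanceThresholds,
    AnnealSchedule,
    EnergyModel,
    accept,
    anneal,
)
from .ensemble_metrics import permuted_backbone_rmsd
from .model_core import Conformer, SymmetryModel
from .restraint_engine import (
    InterfacePin,
    RestraintSet,
    hbond_restraints,
    restraints_from_peaks,
    symmetrize,
)

__all__ = [
    "InterfaceHypothesis",
    "enumerate_hypotheses",
    "evaluate_hypothesis",
    "resolve_register",
]

logger = logging.getLogger(__name__)

_LABELS = ("intramolecular", "intermolecular")


@dataclass
class InterfaceHypothesis:
    """One complete assignment of interface labels, with its trial record."""

    assignments: dict
    n_trials: int = 0
    accepted: int = 0

    def __post_init__(self):
        for k, v in self.assignments.items():
            if v not in _LABELS:
                raise ValueError(f"interface {k!r}: unknown label {v!r}")


def enumerate_hypotheses(
    interfaces,
    constrain: dict | None = None,
    cap: int = 8,
) -> list:
    """All label assignments over the interfaces (2^k for k free ones).

    ``constrain`` pins a subset of interfaces to fixed labels (the
    sequential strategy: resolve one interface, propagate, repeat).  More
    than ``cap`` free interfaces raises, suggesting sequential mode.
    """
    interfaces = list(interfaces)
    if not interfaces:
        raise ValueError("need at least one interface")
    constrain = dict(constrain or {})
    unknown = set(constrain) - set(interfaces)
    if unknown:
        raise ValueError(f"constrained interfaces not in list: {sorted(unknown)}")
    free = [i for i in interfaces if i not in constrain]
    if len(free) > cap:
        raise ValueError(
            f"{len(free)} free interfaces would give {2 ** len(free)} hypotheses; "
            "pin some with `constrain` (sequential strategy) or raise the cap"
        )
    out = []
    for combo in itertools.product(_LABELS, repeat=len(free)):
        assignment = dict(constrain)
        assignment.update(dict(zip(free, combo)))
        out.append(InterfaceHypothesis({i: assignment[i] for i in interfaces}))
    return out


def _pins_for(hypothesis: InterfaceHypothesis, regions: dict) -> list:
    pins = []
    for label_name, amb in hypothesis.assignments.items():
        ra, rb = regions[label_name]
        pins.append(InterfacePin(ra, rb, amb))
    return pins


def evaluate_hypothesis(
    hypothesis: InterfaceHypothesis,
    peaks,
    regions: dict,
    start: Conformer,
    schedule: AnnealSchedule,
    n_trials: int = 20,
    master_seed: int = 0,
    energy: EnergyModel | None = None,
    thresholds: AcceptanceThresholds | None = None,
    sym: SymmetryModel | None = None,
    extra_restraints: RestraintSet | None = None,
):
    """Run seeded annealing trials under one hypothesis.

    The hypothesis' interface labels are applied to the peak list through
    the ambiguity assignment, extra restraints (hydrogen bonds, torsions)
    are appended unchanged, and trial k runs with seed master_seed + k.
    Annealer failures count as rejections (with a log entry).  Returns
    (accepted_count, accepted_conformers) and records the count on the
    hypothesis.
    """
    sym = sym or SymmetryModel()
    thresholds = thresholds or AcceptanceThresholds()
    pins = _pins_for(hypothesis, regions)
    distance = restraints_from_peaks(peaks, pins)
    torsion = []
    if extra_restraints is not None:
        distance = distance + list(extra_restraints.distance)
        torsion = list(extra_restraints.torsion)
    rset = symmetrize(RestraintSet(distance=distance, torsion=torsion), sym)
    accepted = []
    for k in range(n_trials):
        try:
            c = anneal(
                start, rset, schedule, energy=energy, sym=sym,
                seed=master_seed + k,
            )
        except RuntimeError as err:
            logger.warning(
                "trial %d under %s failed (%s); counted as rejection",
                k, hypothesis.assignments, err,
            )
            continue
        ok, _ = accept(c, thresholds=thresholds)
        if ok:
            c.model_id = k
            accepted.append(c)
    hypothesis.n_trials = n_trials
    hypothesis.accepted = len(accepted)
    return len(accepted), accepted


def resolve_register(
    interfaces: dict,
    peaks,
    start: Conformer,
    schedule: AnnealSchedule,
    n_trials: int = 20,
    master_seed: int = 0,
    constrain: dict | None = None,
    energy: EnergyModel | None = None,
    thresholds: AcceptanceThresholds | None = None,
    sym: SymmetryModel | None = None,
    extra_restraints: RestraintSet | None = None,
    consistency_rmsd: float = 3.0,
) -> dict:
    """Compare all interface hypotheses by acceptance count.

    ``interfaces`` maps label -> (region_a, region_b).  The winner is the
    hypothesis with the most accepted structures; ties at zero give status
    ``unresolved`` (no guess).  The report carries per-hypothesis counts
    and a consistency flag: whether all the winner's accepted structures
    share one strand arrangement (pairwise backbone RMSD after
    chain-permutation superposition below ``consistency_rmsd`` Å).
    """
    regions = dict(interfaces)
    hypotheses = enumerate_hypotheses(list(regions), constrain=constrain)
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses to resolve a register")
    results = []
    for h in hypotheses:
        count, accepted_structs = evaluate_hypothesis(
            h, peaks, regions, start, schedule,
            n_trials=n_trials, master_seed=master_seed,
            energy=energy, thresholds=thresholds, sym=sym,
            extra_restraints=extra_restraints,
        )
        results.append((h, count, accepted_structs))
    counts = [c for _, c, _ in results]
    report = {
        "hypotheses": [
            {"assignments": h.assignments, "accepted": c, "n_trials": h.n_trials}
            for h, c, _ in results
        ],
    }
    if max(counts) == 0:
        report["status"] = "unresolved"
        report["winner"] = None
        report["consistent"] = None
        return report
    best_i = max(range(len(results)), key=lambda i: counts[i])
    winner, count, structs = results[best_i]
    consistent = True
    for a, b in itertools.combinations(structs, 2):
        if permuted_backbone_rmsd(a, b, sym=sym) > consistency_rmsd:
            consistent = False
            break
    report["status"] = "resolved"
    report["winner"] = winner.assignments
    report["winner_accepted"] = count
    report["consistent"] = consistent
    report["accepted_structures"] = structs
    return report
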
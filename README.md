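# prismfold

Structure calculation and binding analysis for **C3-symmetric homotrimeric
proteins studied by solution NMR**, built around the workflow that solved
the trimeric structure of the core-fucosylation-specific mushroom lectin
PhoSL (a 40-residue peptide, ~4.4 kDa per monomer) and characterized its
fucose binding.

A symmetric homotrimer gives one set of NMR resonances, so a NOE
cross-peak between protons of residues *i* and *j* cannot say whether the
contact is within one chain or between chains.  `prismfold` implements
the standard machinery for working through that ambiguity:

* **Restraints** — NOE intensity classes map to upper distance bounds of
  3.5 / 4.5 / 6.0 Å; ambiguous peaks are evaluated with the r⁻⁶
  sum-average d_eff = (Σ d_k⁻⁶)^(−1/6) over all candidate chain pairings;
  every unique restraint is replicated across the three chain frames;
  hydrogen bonds contribute two constraints each (20 donors per monomer →
  120 constraints per trimer).
* **Restrained simulated annealing** — Cartesian Langevin dynamics over
  an idealized covalent topology with flat-bottom distance restraints,
  flat-well torsion restraints, repulsive-only nonbonded term and weak
  non-crystallographic-symmetry (NCS) restraints at 10 kcal mol⁻¹ Å⁻²;
  trial structures are **accepted** iff no distance restraint is violated
  by more than 0.2 Å and no torsion restraint by more than 2°, and the 20
  lowest-energy accepted structures form the ensemble.
* **Interface-register resolution** — each strand-interface hypothesis
  (intramolecular vs intermolecular) is evaluated by seeded annealing
  trials; the hypothesis with more accepted structures wins, mirroring
  the original determination in which the intramolecular reading of the
  closing interface produced no acceptable structure while the
  intermolecular one did.
* **Ensemble statistics** — Kabsch superposition, the unminimized mean
  structure, backbone/heavy-atom precision (RMSD to the mean),
  protein–ligand contact maps (C…C ≤ 4.5 Å hydrophobic, N/O…N/O ≤ 3.5 Å
  hydrogen bonds, pooled over the 60 pockets of a 20-model ensemble with
  ≥ 50 % / ≥ 20 % weight classes), and NH–π geometry of the central
  tryptophan triad.
* **Binding thermodynamics** — fast-exchange chemical-shift-perturbation
  titrations fitted with the exact 1:1 quadratic binding model
  (δ_obs = δ_free + (δ_bound − δ_free)·f_bound), ΔΔG = RT ln(K₁/K₂),
  anomer populations from peak intensities, and saturation-transfer
  difference processing.
* **Synthetic data** — exactly C3-symmetric toy trimers (a strand-swapped
  β-prism surrogate and a three-helix bundle), symmetry-blinded NOE peak
  lists and noisy titration curves, so the whole pipeline is testable
  with known ground truth and no downloads.

## Worked example

Fitting a simulated fucose titration (K_D = 6 mM, 150 µM binding sites,
2 % noise) and converting the published affinities to a free-energy gap:

```python
import numpy as np
from prismfold.synthetic_data import simulate_titration
from prismfold.binding_model import fit_kd, delta_delta_g

grid = np.array([1, 2, 5, 10, 20, 40, 70, 100]) * 1e-3  # mol/L fucose
series = simulate_titration(6e-3, 8.30, 8.05, 1.5e-4, grid,
                            noise_sd=0.005, seed=1)
fit = fit_kd(series)
print(f"K_D = {fit.k_d*1e3:.2f} mM (SE {fit.se_kd*1e3:.2f} mM)")
print(f"ddG(fucose vs glycan) = {delta_delta_g(5.9e-3, 3e-6, 298.15):.2f} kcal/mol")
```

```
K_D = 5.61 mM (SE 0.56 mM)
ddG(fucose vs glycan) = 4.49 kcal/mol
```

The fitted K_D recovers the simulated 6 mM within its standard error, and
the measured mM-scale monosaccharide affinity versus the µM-scale glycan
affinity (a ~2000-fold ratio) corresponds to ~4.5 kcal/mol — the cost
that additional sugar–protein contacts must repay.

Folding a toy trimer from its blinded peak list:

```python
from prismfold.model_core import SymmetryModel
from prismfold.synthetic_data import (ToyTrimerSpec, NoeSimSpec,
    make_toy_trimer, simulate_noes, extended_trimer, toy_interfaces,
    toy_torsion_restraints)
from prismfold.restraint_engine import (InterfacePin, RestraintSet,
    restraints_from_peaks, hbond_restraints, find_hbond_donors, symmetrize)
from prismfold.anneal_engine import AnnealSchedule, anneal, accept

sym = SymmetryModel()
truth = make_toy_trimer(ToyTrimerSpec())          # 3 × 19 residues, exact C3
peaks = simulate_noes(truth, NoeSimSpec())         # chain-blinded NOEs
pins = [InterfacePin(v["regions"][0], v["regions"][1], v["true_label"])
        for v in toy_interfaces(19).values()]
rset = symmetrize(RestraintSet(
    distance=restraints_from_peaks(peaks, pins)
             + hbond_restraints(find_hbond_donors(truth, sym)),
    torsion=toy_torsion_restraints(19)), sym)
out = anneal(extended_trimer(19), rset, AnnealSchedule.desk(), seed=0)
print(accept(out)[0], out.max_dist_violation)
```

There is also a thin CLI (`prismfold simulate / restraints / anneal /
resolve / analyze / fit-kd / report`) over the same functions; every
subcommand honors `--seed` and writes plain-text formats (multi-model
PDB, TSV restraint and titration tables, JSON-lines run logs).

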
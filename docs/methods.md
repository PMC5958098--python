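# Methods

`prismfold` implements the computational workflow used to determine the
solution structure of a small C3-symmetric homotrimeric lectin from
ambiguous NOE data, and to characterize its monosaccharide binding by
fast-exchange titration analysis.  This note records the models, the
defaults and their rationale, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## The structural problem

A symmetric homotrimer gives a single set of NMR resonances: a cross-peak
between protons (i, X) and (j, Y) cannot reveal whether the two protons
belong to the same chain or to different chains.  The pipeline treats this
symmetry blindness explicitly:

* **Restraint construction** (`restraint_engine`).  NOE peaks carry
  residue/atom identities only.  Intensity classes map to upper distance
  bounds of 3.5, 4.5 and 6.0 Å (large/medium/small); the lower bound is a
  1.8 Å van der Waals floor throughout.  Sequential and intra-residue
  peaks are always intramolecular.  Medium- (2 ≤ |i−j| ≤ 4) and long-range
  (|i−j| > 4) peaks are *ambiguous* by default and are evaluated with the
  r⁻⁶ sum-average over every candidate chain pairing, so a restraint is
  satisfied as soon as any symmetry-compatible pairing satisfies it.
  Interface pins can fix specific region pairs to intramolecular or
  intermolecular; by default a pin applies only to backbone-proton (HN/HA)
  peaks, the interstrand contacts that can be assigned confidently, while
  side-chain peaks in the same regions keep their ambiguity.  Every
  restraint is replicated on the three chain frames, so each unique NOE
  yields three constraints.  Hydrogen bonds contribute two constraints
  each (H…acceptor 1.8–2.3 Å; donor heavy atom…acceptor 2.8–3.3 Å —
  conventional NMR values), and 20 donors per monomer therefore give 120
  constraints for the trimer.

* **Annealing** (`anneal_engine`).  Cartesian Langevin dynamics (BAOAB
  integrator, uniform unit masses, capped forces) over a simplified
  covalent topology: harmonic bonds, harmonic 1–3 distances standing in
  for bond angles (plus the omega-locked 1–4 backbone pair), a signed-
  volume chirality term at each Cα, and a repulsive-only soft-sphere
  nonbonded term with floors at 0.8 × the summed van der Waals radii.
  The proton radius (1.15 Å) is chosen so the H–H floor (1.84 Å) sits just
  above the 1.8 Å NOE lower bound.  Restraint terms: flat-bottom harmonics
  on sum-averaged effective distances; flat-well torsion restraints
  (target ± tolerance); a weak NCS term (10 kcal mol⁻¹ Å⁻²) penalizing the
  deviation of each chain from the symmetry-averaged chain after optimal
  superposition.  A small "soft-centre" harmonic (k_center, 1/30 of the
  restraint weight) draws each restrained distance toward its well centre,
  reflecting that an observed NOE implies real proximity; it never
  competes with a genuine bound.  During the schedule the restraint and
  repulsive force constants ramp from soft (0.25× and 0.1×) to full
  strength, the standard annealing device that lets topology rearrange
  while hot and enforces geometry while cooling (torsion wells are
  additionally attenuated during dynamics so chains can still wrap into an
  assembly before stiffening).  Stage temperatures are control parameters,
  not physical temperatures.  The published protocols are expressible as
  configurations (50,000 K / 2,000-step stages for the free trimer;
  1,000 K / 1,000-step stages for the complex); synthetic studies use a
  25,000 K → 1,500 K → 5 K schedule of 1,800 + 1,500 + 1,500 steps, about
  fifteen seconds per trial for the default surrogate.  Minimization then
  proceeds in stages, all on the analytic gradient: a plain L-BFGS pass; a
  weight-boosted polish (restraint weights ×8 then ×25) followed by
  relaxation at the true weights, so that compliance bought by straining
  the covalent geometry springs back and is rejected — the Cartesian
  analogue of the exact geometry torsion-angle dynamics maintains by
  construction; short seeded basin hopping on the violation score (skipped
  for hopeless structures); and a centre-seeking pass with a final
  relaxation.  Violations are always measured at the true weights.

* **Acceptance and selection.**  A trial is accepted iff its maximal
  distance violation is ≤ 0.2 Å and its maximal torsion violation is ≤ 2°
  (inclusive).  Among accepted trials the n = 20 of lowest total energy
  form the ensemble (stable tie-break by trial index).  Seeds: trial k of
  a run uses master_seed + k.

* **Register resolution** (`register_resolver`).  Each interface between
  strand regions is assigned intramolecular or intermolecular; hypotheses
  are enumerated exhaustively (2^k) or sequentially with pins.  Each
  hypothesis is evaluated by seeded annealing trials and the acceptance
  counts are compared; the decision statistic is the count comparison,
  never the absolute counts.  Hydrogen-bond restraints are *not* used at
  this stage — acceptors are determined from the calculated structure
  only after the register is known, as in the original protocol.
  Accepted structures of the winning hypothesis are checked for a single
  strand arrangement (pairwise backbone RMSD under cyclic chain
  relabelling below 3 Å).

  One limitation is inherent to upper-bound-only data at surrogate
  density: with *every* interface read intramolecularly, the trimer can
  dissolve into three compact monomers that satisfy each restraint
  internally, so the register of the *first* interface cannot be decided
  in isolation.  The synthetic register study therefore mirrors the
  sequential strategy — the closing (intermolecular) interface is pinned
  as already determined and the next interface is disputed — under which
  the generating hypothesis is consistently at least as productive of
  accepted structures as the alternative, and usually strictly more.  At
  desk-scale trial counts (a few per hypothesis per seed, against
  thousands in the original work) the strict-win vote is noisy; the
  tested property is "never outscored across master seeds, strictly
  winning in a meaningful fraction".

* **Ensemble statistics** (`ensemble_metrics`).  Kabsch superposition;
  the unminimized mean structure by iterated superposition/averaging to a
  1 × 10⁻⁶ Å mean shift (below PDB coordinate precision); ensemble
  precision as mean ± sd RMSD of members to that mean, on the backbone
  (N, Cα, C′) or all-heavy-atom mask.  Protein–ligand contacts are
  distance-only: C…C ≤ 4.5 Å hydrophobic, N/O…N/O ≤ 3.5 Å hydrogen bond,
  cutoffs inclusive, mixed pairs excluded.  Pooling over the three
  symmetric pockets of every member (60 pockets for a 20-member ensemble)
  gives occurrence fractions, classed ≥ 50 % bold and ≥ 20 % thin.  NH–π
  geometry: distance from each chain's Trp Hε1 to the least-squares plane
  of the six-membered indole ring (CD2, CE2, CE3, CZ2, CZ3, CH2) of the
  cyclically next chain, with an in-ring projection flag.

## Binding model (`binding_model`)

Fast exchange makes the observed shift the population-weighted average of
free and bound states.  The bound fraction uses the exact 1:1 per-site
quadratic solution (numerically stable root), with the excess-ligand
limit L/(L + K_D) when P_tot = 0 or P_tot/K_D < 10⁻³.  The trimer's three
sites are treated as independent and identical; P_tot is the site
concentration (three times the trimer concentration).  `fit_kd` fits
(K_D, δ_free, δ_bound) by Levenberg–Marquardt least squares in log-K_D,
multi-started over a geometric K_D grid spanning the sampled ligand range;
the K_D standard error comes from the Jacobian at the optimum by the
delta method.  A series whose shift range is below the noise floor is
reported unidentifiable rather than fitted.  ΔΔG = RT ln(K1/K2) with
R = 1.987 × 10⁻³ kcal mol⁻¹ K⁻¹; the default temperature is 298.15 K
(the headline mM-vs-µM comparison corresponds to ~4.5 kcal/mol at 298 K,
although the experiments themselves ran at 308 K — both are supported).
Anomer populations are normalized peak intensities (optionally per-proton);
the saturation-transfer difference helper subtracts on- from off-resonance
spectra, flags positive peaks (scipy peak finding at 5 % of the maximal
difference amplitude), and converts their intensities to bound-state
populations.

## Synthetic data (`synthetic_data`)

The generator must produce inputs with the statistical structure the
pipeline assumes — exact C3 symmetry, blinded NOEs, noisy titrations —
with known ground truth.

* **Toy trimers.**  The default `beta_prism_surrogate` is a parametric
  strand-swapped prism: each 19-residue chain contributes three 5-residue
  strands (2-residue glycine linkers) to a ring of nine strands around
  the three-fold axis (spacing 4.9 Å, ring radius ≈ 7.2 Å).  The third
  strand of each chain pairs with the first strand of the *next* chain,
  so the closing interface is genuinely intermolecular — the situation in
  which intra- and inter-chain NOEs become indistinguishable.  Strand
  carbonyls are oriented tangentially (with the descending strand's pleat
  parity flipped) so backbone hydrogen bonds form across all three
  interfaces.  Chains carry N, HN, Cα, Hα, Cβ, a single pseudo-β proton,
  C′ and O; the assembled design is refined against the covalent energy
  terms under an exact C3 projection (only chain A is free; B and C are
  its 120°/240° rotations), with near-miss hydrogen bonds pulled into
  ideal geometry, so the generated model is exactly symmetric and
  satisfies its own restraints with zero violation.  A parallel
  three-helix bundle surrogate is also provided.

* **Blinded NOEs.**  Every proton pair within 5.0 Å emits a peak recording
  residue/atom identities only; duplicate intra/inter peaks merge keeping
  the tighter class.  Class edges 2.7/3.6/5.0 Å sit at or below the
  3.5/4.5/6.0 Å bounds, so the generator satisfies every emitted restraint
  exactly — the conservation check for the whole restraint pipeline.
  A false-negative rate simulates missed peaks.

* **Torsion restraints.**  Backbone φ/ψ restraints (template value ± 35°)
  on torsions interior to each strand stand in for experimentally
  determined torsions.  They matter beyond realism: torsion angles are
  chirality-sensitive, and distance bounds alone cannot distinguish a
  fold from its mirror image.

* **Titrations.**  The fast-exchange model plus seeded Gaussian noise.
  The recovery study uses K_D = 6 mM, a 0.25 ppm shift change, 150 µM
  sites and an 8-point grid to 100 mM — the concentration scales of the
  real titration — with noise at 2 % of the shift range.

### What the synthetic experiments show — and what they do not

Fold recovery (blinded NOEs + hydrogen bonds + torsions, 20 seeded trials
from an extended, symmetric start) demonstrates that the annealer can
solve the blinded-assignment problem: the best trial reaches the truth to
about 1 Å backbone RMSD.  Register resolution demonstrates the
acceptance-count contrast between the generating interface hypothesis and
its alternative.  Two caveats are inherent to distance data.  First, the
data admit a *reversed-winding* assembly (the mirror-like topology with
native local geometry); such trials can pass the acceptance filter, and
the recovery statistic is therefore the best RMSD over trials, not the
RMSD of every accepted trial.  Second, a surrogate with one pseudo-proton
per side chain is far sparser than real data (~11 peaks per residue here;
several times denser in the real spectra), so acceptance rates and
hypothesis contrasts are noisier than the published 8-of-3000 versus
0-of-3000.  The toy results validate the machinery, not the information
content of any particular real data set.

## Numerical choices

* Force constants (kcal/mol Å⁻² unless noted): bonds 300, 1–3 distances
  100, chirality 50 (Å⁻⁶), repulsion 100, NOE 30, torsions 60 rad⁻²,
  NCS 10, soft-centre 1.
* Langevin dynamics: dt = 0.02, friction 2.0, per-atom force cap
  100 kcal/mol/Å, temperatures linearly interpolated within stages.
* Repulsion uses a KD-tree neighbour list with a 1 Å skin, rebuilt on
  large displacements; exclusions are all pairs within three covalent
  bonds.
* The annealing gradient treats the NCS superposition rotations as
  constants (exact at the superposition optimum) — the standard NCS force
  approximation.
* Degenerate inputs: empty restraint sets anneal fine (zero restraint
  energy); a single-contributor sum-average is the plain distance;
  superposition requires ≥ 3 non-collinear atoms; ensembles need ≥ 2
  members for a mean structure.
* Ties in ensemble selection break by trial index; hypothesis ties at
  zero acceptance give status "unresolved" rather than a guess.

## Known limitations

* The annealer is a Cartesian surrogate for torsion-angle dynamics; its
  absolute energies are not comparable to any published force field, and
  the van der Waals statistics of deposited ensembles are out of scope.
* The coarse residue representation (no real side chains beyond Cβ plus a
  pseudo-proton) cannot reproduce packing-level discrimination; rotamer
  (χ¹/χ²) restraints are expressible but only exercised on models that
  carry the corresponding atoms.
* Distance-only data cannot set global handedness; torsion restraints
  mitigate but do not eliminate reversed-winding solutions (see above).
* The minimized-mean-structure protocol of the original work is not
  specified there; this package provides the unminimized mean and labels
  it as such.
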
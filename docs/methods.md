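# Methods

## Pose model

A ligand pose is a real vector of `7 + T` genes: translation (Å),
orientation as a unit quaternion stored `(w, x, y, z)`, and `T` torsion
angles in `(-π, π]`.  Decoding applies torsions depth-first from the PDBQT
ROOT block outward, in the order the BRANCH records declare them, each
rotation using the already-torsioned axis coordinates; the whole ligand is
then rotated about the centroid of the root-block atoms and translated.
The pivot choice is arbitrary but fixed — any constant pivot yields the
same reachable pose set — and is documented here because RMSD and box
semantics depend on it.  Decoding is exact rigid motion: bond lengths and
all angles not spanning a rotatable bond are preserved to machine
precision, which the property tests assert at 1e-9 Å.

Quaternions are renormalized after every variation operator (tolerance
1e-9); a decoder receiving a non-unit quaternion renormalizes and warns
rather than failing, because crossover can legitimately cut through the
orientation block.  Torsions are wrapped to `(-π, π]` after mutation.

RMSD is the in-frame (no superposition) heavy-atom root-mean-square
deviation — the docking community's convention for comparing a docked pose
with the crystal pose in the fixed receptor frame.  Hydrogens are excluded;
no graph-automorphism symmetry correction is applied (a stated non-goal).
A docking is valid iff RMSD < 2.0 Å, strictly.

## Scoring function

The objective is an AutoDock4-style semi-empirical pairwise sum over
intermolecular atom pairs plus intra-ligand pairs:

    E = W_vdw  Σ (A/r¹² − B/r⁶)            A = ε R¹²,  B = 2 ε R⁶
      + W_hb   Σ (C/r¹² − D/r¹⁰)           C = 5 ε_hb R_hb¹², D = 6 ε_hb R_hb¹⁰
      + W_elec Σ 332.06363 q_i q_j / (ε(r) r)
      + W_ds   Σ (S_i V_j + S_j V_i) exp(−r²/2σ²)     σ = 3.5 Å
      + W_tor · T

with the published AutoDock 4.2 weights (0.1662, 0.1209, 0.1406, 0.1322,
0.2983), Lorentz–Berthelot mixing of the per-type `Rii/εii` table shipped
in `data/ad4_params.dat`, `S_i = solpar_i + 0.01097·|q_i|`, and the
Mehler–Solmajer sigmoidal distance-dependent dielectric
`ε(r) = A + B/(1 + k e^{−λBr})` with `A = −8.5525`, `ε₀ = 78.4`,
`k = 7.7839`, `λ = 0.003627`.  Direct pairwise summation replaces
AutoDock's grid maps; no bit-compatibility with AutoDock energies is
claimed or needed, since all quantitative claims are made on synthetic
fixtures scored by this same function.

Numerical guards: pairs beyond the 8 Å cutoff contribute exactly zero;
below 0.5 Å the distance is clamped and a linear ramp (100 kcal mol⁻¹ Å⁻¹)
is added; and the repulsive 12-6/12-10 pair term is capped at 100 kcal/mol
(`clash_cap`).  The cap matters for the search, not the chemistry: without
it, clashing poses differ by ~10⁹ in energy and rank selection degenerates
to noise, while with it a generational search can order bad poses by how
bad they are.  No genome inside the search box can produce NaN/Inf.

Intra-ligand pairs follow AutoDock's exclusion rule — 1-2, 1-3 and 1-4
interactions are dropped (graph distance ≥ 4 bonds) and only pairs whose
separation can change under the torsions (different rigid fragments) are
summed.  Including 1-4 pairs would attach a large constant clash penalty to
every compact all-heavy-atom ligand, since a 1-4 distance can never reach
the 4 Å carbon–carbon optimum.

Two implementations exist: a vectorized numpy reference (`BoundScorer`)
and a numba-compiled fused decode+score kernel used by the search drivers.
They agree to better than 1e-12 on random systems (asserted in the tests,
along with agreement with an independent naive double-loop oracle).

## Search

`run_cepga` is a generational loop: linear rank selection (pressure
s = 1.5, so with P = 2 the better parent is chosen with probability 0.75),
one-point crossover at uniform gene boundaries (rate 0.8), crossover
elitist preservation, Gaussian real mutation (per-gene rate 0.05;
σ = 2.0 Å translations, 0.35 rad torsions, small random rotation composed
with the quaternion), and Solis–Wets local search on 6% of the population
(300 iterations, ρ₀ = 1.0, expand ×2 after 4 consecutive successes,
contract ×0.5 after 4 failures, opposite step tried on failure, strict
Lamarckian write-back).  A final polish applies the same local search to
the best-ever pose before reporting.  CEP uses ⌈θ·P⌉ elites (θ = 0.05
default, midpoint of the 0.01–0.1 range; ceiling so at least one elite
always exists) whose preserved parents replace distinct uniformly drawn
non-elite members; configurations with `3⌈θP⌉ > P` are rejected up front.
Generation-0 individuals and re-injected parents have no recorded
ancestry and self-parent if they become elites.  Mutation skips the
current generation's elites, keeping preservation meaningful.

All randomness flows through one seeded `numpy.random.Generator` in a
fixed draw order (selection, crossover cut, CEP slots, mutation, local
search), so a config plus seed reproduces a run bitwise.  The evaluation
context counts every objective call against the budget, records the
best-so-far trace at strict improvements (hence strictly decreasing by
construction), and raises a budget-exhausted signal that unwinds cleanly
to "return the best pose seen".  Cached energies (untouched individuals,
re-injected parents) do not re-count.

The defaults document the full benchmark budget (P = 50, 27,000
generations, 1.5×10⁶ evaluations per docking, termination on whichever
limit is hit first).  `SearchConfig.desk_scale()` is the reduced budget
used by the test suite and benchmarks: P = 50, 500 generations, 10⁶
evaluations, with the local search applied to a quarter of the population
instead of 6% — with 54× fewer generations, the denser per-generation
refinement spends a comparable evaluation total inside the available
generations.  A ten-run experiment completes in minutes on one core with
the algorithmics untouched.

`run_ga` disables CEP and (by default) local search but shares every other
operator and the RNG discipline, so CEPGA-vs-GA differences measure the
mechanism, not implementation drift.  `ga+ls` (GA plus local search) is
the third arm, approximating a Lamarckian GA baseline.

## Synthetic fixtures

The generator builds docking problems whose global optimum is known by
construction, standing in for crystal complexes:

* **Ligand** — a rigid 3-atom root block plus one branch per rotatable
  bond (up to 15), grown with clearance-maximizing placement so the
  template is clash-free and elongated.  Atoms are carbon except
  hydrogen-bond anchors: one OA on a root atom (pins orientation) and one
  on each branch terminus (pins the torsion state).  Partial charges are
  mild (|q| ∈ [0.1, 0.2]): strong charges would make the charge-dependent
  solvation parameter positive and ring the pocket with a desolvation
  barrier that chokes the binding funnel.
* **Planted pose** — translation in the central half of the box, uniform
  random orientation, torsions chosen as the best of 300 random draws by
  intra-ligand energy (a crystal conformer is not self-clashing).
* **Pocket** — a concave half-shell: up to 4 receptor atoms per ligand
  heavy atom at pair-minimum contact distance (HD partners at 1.9 Å for
  acceptors, carbons at the Lennard-Jones minimum otherwise), each site
  accepted only if it attracts the whole pose, with ≥ 2.6 Å spacing, and
  only on the hemisphere away from the root anchor — the open mouth gives
  the search a downhill approach path, while the back wall makes shifted
  or flipped poses clash.  The search box (half-extent 4 Å) is centered
  between pocket and mouth, as a docking box over a known site would be.
* **Relaxation** — each shell atom is optimal against the pose, but the
  joint optimum of the assembled pocket is slightly displaced, so the
  planted genome is relaxed (Powell restarts interleaved with a
  contracting random walk) and the relaxed pose becomes the reference.
* **Quality control** — a candidate instance is accepted only if probe
  dockings (3 short screens, then 6 full-budget probes, fresh seeds
  disjoint from any test seed) never find an energy more than 0.05 below
  the planted reference away from it (no deeper decoy) and recover the
  pose within 2 Å in all full probes.  Instances failing the screen are
  regenerated from a derived seed; the loop is deterministic, so one spec
  always yields one fixture, and fixture files written twice are
  byte-identical.  For the canonical benchmark specs the first passing
  attempt index, found by this same screening during development, is
  recorded in the generator so rebuilding starts at the known-good
  instance (which is still re-verified by the probes); unlisted specs
  simply scan from the first attempt.  `quality_control=False` skips the
  probing for callers that need a docking problem rather than a certified
  benchmark.

What the fixtures do *not* emulate: chemistry (valence, protonation,
aromaticity), receptor flexibility, solvent structure, and the size of
real binding sites.  Passing the recovery benchmarks therefore shows that
the search machinery finds planted global basins of an AutoDock-style
landscape at desk scale — it does not predict accuracy on real complexes.

The analytic landscapes (`bowl`, `multimodal` with its minimum of −1 at
the documented offset, and the 11³-state `lattice`) exercise the
operators alone; the lattice is small enough that exhaustive enumeration
provides a true global optimum for oracle tests.

## Benchmarking and statistics

`run_experiment` runs R independent seeded dockings per (instance,
algorithm) cell (seeds `base_seed + run_index`, recorded for replay),
aggregates lowest energy, smallest RMSD and the success count under the
strict 2 Å rule, and validates every trace (strictly decreasing energy,
strictly increasing evaluation counts) on ingest; a violated trace is a
hard error because it indicates an evaluation-accounting bug.  A crashed
run is recorded as a failed cell and the experiment continues.

Box statistics follow the Tukey convention: quartiles by linear
interpolation, whisker edges at the most extreme values within 1.5 IQR.

Algorithm pairs are compared with a one-sided Wilcoxon–Mann–Whitney
rank-sum test on final energies ("a yields lower energies than b"): exact
enumeration when both arms have ≤ 10 tie-free values, otherwise the normal
approximation without continuity correction.  The two conventions differ
in one detail worth documenting: asymptotic one-sided p-values of the two
directions sum to exactly 1 (mirrored off-diagonal structure), while exact
ones sum to 1 plus the null point mass at the observed statistic — a
property of any exact discrete test, not an implementation artifact.
Completely tied samples report p = 0.5 with a tie flag.

## File formats

PDBQT in the AutoDock 4 fixed-width dialect: coordinates in columns 31–54,
partial charge in 67–76, atom type in 78–79; ligands carry
ROOT/ENDROOT, nested BRANCH/ENDBRANCH blocks and TORSDOF.  Parsing is
tolerant of trailing whitespace and fails loudly (with line numbers) on
shifted columns or unknown atom types; waters (HOH/WAT) are dropped from
receptors with a logged count.  PDBQT carries no bond table, so ligand
bonds are perceived by distance (1.9 Å heavy–heavy, 1.3 Å to hydrogen)
plus the declared BRANCH axes.  Coordinates print at 1e-3 Å, which bounds
how exactly a re-read pose can reproduce a reported energy (~1e-2 in
practice near a minimum); the run tables carry energies at full precision.

## Known limitations

* Table-level agreement with AutoDock on real PDB complexes is out of
  scope by design: that requires AutoDock's grid-map force field and
  external structures.
* The fixture generator's quality-control loop uses the search itself as
  a probe; it certifies recoverability *by this engine at the desk-scale
  budget*, which is the property the benchmarks need, but it is not an
  independent proof that the planted pose is the global optimum.
* Symmetry-corrected RMSD is not implemented; for the synthetic ligands
  (distinct anchors, asymmetric charges) pose degeneracy is broken by
  construction.
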
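# cepdock

A small, self-contained protein–ligand docking engine built around **CEPGA**
— a real-coded genetic algorithm with a *crossover elitist preservation*
(CEP) mechanism and Lamarckian local search — together with the scoring,
pose-model, file-format and benchmarking machinery needed to study the
search algorithm end to end.

## The problem

Docking predicts the bound pose of a small molecule in a protein's binding
site by minimizing a scoring function over the ligand's pose space.  A pose
is encoded as a real vector of `7 + T` genes — three translations (Å), a
unit quaternion `(w, x, y, z)`, and `T` torsion angles, one per rotatable
bond — and is judged by the heavy-atom RMSD to the reference (crystal)
pose, computed in the receptor frame; a docking is *valid* iff RMSD < 2.0 Å.

## The search algorithm

CEPGA is a generational GA (linear rank selection, one-point crossover,
Gaussian real mutation) with two additions:

* **CEP** — after the offspring generation is evaluated, the best
  `⌈θ·P⌉` individuals (θ ∈ [0.01, 0.1], population `P`) are recorded as
  elites together with the father and mother that produced each of them.
  Those `2⌈θ·P⌉` preserved parents are re-injected into the population,
  replacing distinct uniformly chosen non-elite members; elites themselves
  are never displaced.  Parents of a new best individual evidently carry
  good gene blocks, so they get another chance to recombine.
* **Lamarckian local search** — a Solis–Wets adaptive random walk refines a
  fraction of each generation (default 6%, up to 300 iterations) and writes
  the improved genome back into the individual.

The ablation baseline `run_ga` shares every operator with CEP and local
search disabled, so paired runs isolate the contribution of the mechanism.

## Scoring

An AutoDock4-style semi-empirical pairwise energy, evaluated by direct
summation (no grid maps):
12-6 dispersion/repulsion, 12-10 hydrogen bonds, screened Coulomb
electrostatics with the Mehler–Solmajer sigmoidal dielectric, Gaussian
desolvation, and a torsional penalty `W_tor·T`, with the published
AutoDock 4.2 weights as defaults.  It is a faithful *style* reimplementation,
not a bit-compatible AutoDock replacement.

## Synthetic benchmarks with known answers

Real complexes give no ground truth for a search algorithm, so the
`synthetic` module builds desk-scale fixtures with a *planted* optimum: a
random branched ligand (0–15 rotatable bonds), a randomly drawn "crystal"
pose, and a concave pocket of complementary receptor atoms around that pose
(hydrogen-bond partners for the polar anchors, van-der-Waals contacts
elsewhere, open mouth on one side).  Candidate instances are probed with
short docking runs at build time and regenerated until no probe finds a
basin deeper than the planted one and the pose is reliably recoverable —
the generator guarantees its contract rather than trusting one random
geometry.  Analytic landscapes (quadratic bowl, multimodal, 11³-state
lattice with an exhaustive brute-force oracle) test the operators
independently of the molecular machinery.

## Worked example

```sh
cepdock synth --torsions 2 --seed 0 --out fixtures/
cepdock dock --receptor fixtures/receptor.pdbqt --ligand fixtures/ligand.pdbqt \
             --reference fixtures/reference.pdbqt --generations 500 --seed 1 --out run/
```

prints, for the planted-pocket fixture above (8 ligand atoms, 19 pocket
atoms):

```
cepga: best energy -2.1043  RMSD 0.26  (276191 evaluations)
```

i.e. the search recovered a pose 0.26 Å from the planted reference (a valid
docking under the 2 Å rule) with the lowest energy found in ~2.8×10⁵
scoring calls.  `run/` then contains the best pose as PDBQT (REMARK lines carry
energy, RMSD, seed and a config hash), a TSV row table, and the
evaluations-vs-best-energy trace.  `cepdock compare` runs several
algorithms R times each and writes the aggregate table plus one-sided
rank-sum p-values; `cepdock bench` does the same over a set of synthetic
fixtures and can render convergence and box plots.

Library use mirrors the CLI:

```python
from cepdock import SearchConfig, run_cepga
from cepdock.synthetic import FixtureSpec, make_fixture

fx = make_fixture(FixtureSpec(n_torsions=2, rng_seed=0))
summary = run_cepga(fx.problem(), SearchConfig.desk_scale(), seed=1)
print(summary.best_energy, summary.best_rmsd)
```

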
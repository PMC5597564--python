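"""Real-coded genetic search with a Crossover Elitist Preservation mechanism.

The engine's central idea: when the offspring generation is evaluated, the
best ``ceil(theta * P)`` individuals are recorded as elites together with the
two parents that produced each of them.  Those preserved parents are
re-injected into the offspring population, replacing distinct uniformly
chosen non-elite members — elites themselves are never displaced.  Because
the parents of a new best individual evidently carry good gene blocks, they
get a second chance to recombine, which sharpens the crossover without
shrinking the population.

Around that mechanism sit standard real-coded GA machinery (linear rank
selection, one-point crossover, Gaussian real mutation) and an optional
Lamarckian Solis-Wets local search whose improvements are written back into
the genome.  ``run_cepga`` is the full algorithm; ``run_ga`` is the ablation
baseline with CEP and local search disabled but every other operator shared.

All randomness flows through a single seeded ``numpy.random.Generator``:
identical config + seed gives a bitwise-identical run trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .pose import (
    Genome,
    LigandTopology,
    ReceptorModel,
    ligand_rmsd,
    decode,
    random_unit_quaternion,
    wrap_angle,
)
from .scoring import (
    BudgetExhausted,
    EnergyModelParams,
    EvaluationContext,
    make_docking_objective,
)

__all__ = [
    "SearchConfig",
    "SearchSpace",
    "BoxSpace",
    "PoseSpace",
    "Problem",
    "Individual",
    "ElitistRecord",
    "RunSummary",
    "rank_select",
    "one_point_crossover",
    "real_mutation",
    "cep_update",
    "local_search",
    "run_cepga",
    "run_ga",
    "dock",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SearchConfig:
    """Search hyper-parameters.

    Defaults document the full benchmark budget (population 50, 27,000
    generations, 1.5e6 evaluations per docking); tests and desk-scale
    benchmarks pass reduced generation counts through ``replace``/kwargs.
    """

    pop_size: int = 50
    max_generations: int = 27_000
    max_evaluations: int = 1_500_000
    theta: float = 0.05  # elite fraction, midpoint of the 0.01-0.1 range
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05  # per-gene perturbation probability
    sigma_translation: float = 2.0  # Å
    sigma_rotation: float = 0.35  # rad, small-rotation mutation of orientation
    sigma_torsion: float = 0.35  # rad
    selection_pressure: float = 1.5  # linear-rank pressure s in [1, 2]
    ls_frequency: float = 0.06  # fraction of the population refined per generation
    ls_max_iter: int = 300
    ls_rho0: float = 1.0
    ls_rho_min: float = 1e-3
    ls_success_limit: int = 4
    ls_failure_limit: int = 4
    ls_expand: float = 2.0
    ls_contract: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2 (crossover needs 2 parents)")
        if not (0.01 <= self.theta <= 0.1):
            raise ValueError(f"theta must lie in [0.01, 0.1], got {self.theta}")
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if not (1.0 <= self.selection_pressure <= 2.0):
            raise ValueError("linear-rank pressure must lie in [1, 2]")
        if self.max_generations < 0 or self.max_evaluations < 1:
            raise ValueError("non-positive budget")
        k = self.n_elites
        if 3 * k > self.pop_size:
            raise ValueError(
                f"infeasible CEP config: {k} elites + {2 * k} preserved parents "
                f"exceed population {self.pop_size}"
            )

    @property
    def n_elites(self) -> int:
        """ceil(theta * P): the elite count; preserved parents number twice it."""
        return math.ceil(self.theta * self.pop_size)

    def replace(self, **kw) -> "SearchConfig":
        return replace(self, **kw)

    @classmethod
    def desk_scale(cls, **overrides) -> "SearchConfig":
        """Reduced benchmark budget (population 50, 500 generations, 1e6
        evaluations) used for desk-scale synthetic benchmarks and the test
        suite.  With 54x fewer generations than the full budget, a denser
        local search per generation (a quarter of the population instead of
        6%) spends the same total evaluations in the available generations;
        every other parameter keeps its default."""
        base: dict = dict(
            max_generations=500, max_evaluations=1_000_000, ls_frequency=0.25
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SearchConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)})
        )


# ---------------------------------------------------------------------------
# search spaces


class SearchSpace:
    """Gene layout of a problem: sampling, mutation and repair of genomes."""

    length: int

    def random(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def mutate(
        self, vec: np.ndarray, cfg: SearchConfig, rng: np.random.Generator
    ) -> np.ndarray:
        raise NotImplementedError

    def repair(self, vec: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def mutate_batch(self, mat, cfg, rng):
        out = np.stack([self.mutate(row, cfg, rng) for row in mat])
        return out, np.any(out != mat, axis=1)

    def repair_after_cut(self, child: np.ndarray, cut: int) -> np.ndarray:
        return self.repair(child)


class BoxSpace(SearchSpace):
    """Plain rectangular real space (used by synthetic test landscapes)."""

    def __init__(self, lower: Sequence[float], upper: Sequence[float]):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if self.lower.shape != self.upper.shape or np.any(self.lower >= self.upper):
            raise ValueError("invalid box bounds")
        self.length = self.lower.size

    def random(self, rng):
        return rng.uniform(self.lower, self.upper)

    def mutate(self, vec, cfg, rng):
        mask = rng.random(self.length) < cfg.mutation_rate
        step = rng.normal(0.0, cfg.sigma_translation, size=self.length)
        return self.repair(np.where(mask, vec + step, vec))

    def mutate_batch(self, mat, cfg, rng):
        """Mutate many genomes at once; returns (new matrix, changed-row mask)."""
        mask = rng.random(mat.shape) < cfg.mutation_rate
        step = rng.normal(0.0, cfg.sigma_translation, size=mat.shape)
        out = np.clip(np.where(mask, mat + step, mat), self.lower, self.upper)
        return out, np.any(out != mat, axis=1)

    def repair(self, vec):
        return np.clip(vec, self.lower, self.upper)

    def repair_after_cut(self, child, cut):
        return child  # any cut of two in-box genomes stays in the box


class PoseSpace(SearchSpace):
    """Docking genome space: 3 translations bounded by the search box,
    a unit quaternion, and T wrapped torsions.

    Translations are expressed as offsets of the ligand root centroid, so the
    box constraint clamps ``root_centroid + t`` into the receptor box.
    """

    def __init__(self, topo: LigandTopology, receptor: ReceptorModel):
        self.n_torsions = topo.n_torsions
        self.length = 7 + self.n_torsions
        centroid = topo.root_centroid
        center, half = receptor.box_center, receptor.box_half_extent
        self.t_lower = center - half - centroid
        self.t_upper = center + half - centroid

    def random(self, rng):
        t = rng.uniform(self.t_lower, self.t_upper)
        q = random_unit_quaternion(rng)
        tor = rng.uniform(-np.pi, np.pi, size=self.n_torsions)
        return np.concatenate([t, q, tor])

    def mutate(self, vec, cfg, rng):
        out = vec.copy()
        # one Bernoulli draw per gene; the orientation block consumes the
        # draw of its first gene and mutates as a whole small rotation
        mask = rng.random(self.length) < cfg.mutation_rate
        t_mask = mask[:3]
        if np.any(t_mask):
            out[:3] = np.where(
                t_mask, out[:3] + rng.normal(0.0, cfg.sigma_translation, 3), out[:3]
            )
        if mask[3]:
            out[3:7] = _compose_small_rotation(out[3:7], cfg.sigma_rotation, rng)
        tor_mask = mask[7:]
        if np.any(tor_mask):
            steps = rng.normal(0.0, cfg.sigma_torsion, self.n_torsions)
            out[7:] = np.where(tor_mask, out[7:] + steps, out[7:])
        return self.repair(out)

    def mutate_batch(self, mat, cfg, rng):
        """Mutate many pose genomes at once (same per-gene semantics as
        ``mutate``, vectorized); returns (new matrix, changed-row mask)."""
        n, L = mat.shape
        out = mat.copy()
        mask = rng.random((n, L)) < cfg.mutation_rate
        t_steps = rng.normal(0.0, cfg.sigma_translation, (n, 3))
        out[:, :3] = np.clip(
            np.where(mask[:, :3], out[:, :3] + t_steps, out[:, :3]),
            self.t_lower,
            self.t_upper,
        )
        for i in np.nonzero(mask[:, 3])[0]:
            out[i, 3:7] = _compose_small_rotation(
                out[i, 3:7], cfg.sigma_rotation, rng
            )
        if self.n_torsions:
            tor_steps = rng.normal(0.0, cfg.sigma_torsion, (n, self.n_torsions))
            out[:, 7:] = np.where(
                mask[:, 7:], wrap_angle(out[:, 7:] + tor_steps), out[:, 7:]
            )
        return out, np.any(out != mat, axis=1)

    def repair(self, vec):
        out = vec.copy()
        out[:3] = np.clip(out[:3], self.t_lower, self.t_upper)
        norm = np.linalg.norm(out[3:7])
        out[3:7] = out[3:7] / norm if norm > 0 else np.array([1.0, 0, 0, 0])
        if self.n_torsions:
            out[7:] = wrap_angle(out[7:])
        return out

    def repair_after_cut(self, child, cut):
        # only a cut through the orientation block can invalidate a child
        # assembled from two valid genomes
        if 3 < cut < 7:
            q = child[3:7]
            n = math.sqrt(q @ q)
            if n > 0:
                child[3:7] = q / n
            else:
                child[3:7] = (1.0, 0.0, 0.0, 0.0)
        return child


def _compose_small_rotation(
    q: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Compose quaternion q with a random rotation of Gaussian magnitude."""
    axis = rng.normal(size=3)
    n = np.linalg.norm(axis)
    axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
    angle = rng.normal(0.0, sigma)
    h = 0.5 * angle
    dw, dv = math.cos(h), math.sin(h) * axis
    w, v = q[0], q[1:]
    out = np.empty(4)
    out[0] = dw * w - dv @ v
    out[1:] = dw * v + w * dv + np.cross(dv, v)
    out /= np.linalg.norm(out)
    return out


@dataclass
class Problem:
    """An objective over a search space.  ``reference_coords``/``topo`` are
    set for docking problems so the driver can report a pose RMSD."""

    space: SearchSpace
    objective: Callable[[np.ndarray], float]
    topo: LigandTopology | None = None
    reference_coords: np.ndarray | None = None
    name: str = "problem"

    @classmethod
    def docking(
        cls,
        topo: LigandTopology,
        receptor: ReceptorModel,
        params: EnergyModelParams | None = None,
        reference_coords: np.ndarray | None = None,
        name: str = "docking",
    ) -> "Problem":
        return cls(
            space=PoseSpace(topo, receptor),
            objective=make_docking_objective(topo, receptor, params),
            topo=topo,
            reference_coords=reference_coords,
            name=name,
        )


# ---------------------------------------------------------------------------
# individuals


_id_counter = 0


def _next_id() -> int:
    global _id_counter
    _id_counter += 1
    return _id_counter


@dataclass
class Individual:
    """A genome with its cached energy and the parent bookkeeping CEP needs.

    ``parents`` holds lightweight snapshots (genome + energy, no deeper
    ancestry) of the two parents that produced this individual; ``None`` for
    generation-0 members and for re-injected parents, which self-parent if
    they ever become elites.
    """

    genome: np.ndarray
    energy: float | None = None
    parents: tuple["Individual", "Individual"] | None = None
    id: int = field(default_factory=_next_id)

    @property
    def parent_ids(self) -> tuple[int, int] | None:
        return None if self.parents is None else (
            self.parents[0].id,
            self.parents[1].id,
        )

    def snapshot(self) -> "Individual":
        """Ancestry-free copy used as a parent record (breaks the genealogy
        chain so long runs do not retain every past generation)."""
        return Individual(genome=self.genome, energy=self.energy, parents=None,
                          id=self.id)


@dataclass(frozen=True)
class ElitistRecord:
    """An elite of the current generation together with its preserved
    father and mother."""

    elite: Individual
    father: Individual
    mother: Individual


@dataclass
class RunSummary:
    """Outcome of one search run."""

    best_genome: np.ndarray
    best_energy: float
    best_rmsd: float | None
    n_evaluations: int
    n_generations: int
    trace: list[tuple[int, float]]
    seed: int
    algorithm: str


# ---------------------------------------------------------------------------
# operators


def _rank_probabilities(n: int, s: float) -> np.ndarray:
    """Linear ranking probabilities, best rank first:
    p_i = (s - (2s-2) * i / (n-1)) / n."""
    if n == 1:
        return np.ones(1)
    i = np.arange(n)
    return (s - (2.0 * s - 2.0) * i / (n - 1)) / n


def _sorted_by_energy(members: list[Individual]) -> list[Individual]:
    # stable: ties keep first-occurrence order
    return sorted(members, key=lambda ind: ind.energy)


def rank_select(
    members: list[Individual],
    rng: np.random.Generator,
    pressure: float = 1.5,
    size: int | None = None,
) -> Individual | list[Individual]:
    """Linear rank ('sort') selection: individuals are ranked by energy
    ascending and drawn with linearly decreasing probability in rank, so a
    strictly lower energy always means a strictly higher selection chance.

    Returns one individual, or a list when ``size`` is given.
    """
    if not members:
        raise ValueError("cannot select from an empty population")
    ranked = _sorted_by_energy(members)
    probs = _rank_probabilities(len(ranked), pressure)
    idx = rng.choice(len(ranked), size=1 if size is None else size, p=probs)
    picks = [ranked[i] for i in idx]
    return picks[0] if size is None else picks


def one_point_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
    space: SearchSpace | None = None,
    cut: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-point crossover at a uniform gene boundary ``k in {1..L-1}``.

    Children are repaired afterwards (quaternion renormalized if the cut
    splits the orientation block).  ``cut`` forces a boundary for testing.
    Genomes of length < 2 are returned as copies.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parent genome lengths differ")
    L = a.size
    if L < 2:
        return a.copy(), b.copy()
    k = int(rng.integers(1, L)) if cut is None else cut
    if not 1 <= k <= L - 1:
        raise ValueError(f"cut point {k} outside 1..{L - 1}")
    child_a = np.concatenate([a[:k], b[k:]])
    child_b = np.concatenate([b[:k], a[k:]])
    if space is not None:
        child_a = space.repair_after_cut(child_a, k)
        child_b = space.repair_after_cut(child_b, k)
    return child_a, child_b


def real_mutation(
    genome: np.ndarray,
    cfg: SearchConfig,
    rng: np.random.Generator,
    space: SearchSpace,
) -> np.ndarray:
    """Gaussian real mutation: each gene is perturbed independently with
    probability ``cfg.mutation_rate``; translations are clamped to the box,
    torsions wrapped, the orientation block perturbed by a small random
    rotation and renormalized."""
    return space.mutate(np.asarray(genome, dtype=float), cfg, rng)


def cep_update(
    offspring: list[Individual],
    elite_records: Sequence[ElitistRecord],
    rng: np.random.Generator,
    slots: Sequence[int] | None = None,
) -> list[Individual]:
    """Crossover elitist preservation.

    The preserved father and mother of every elite replace distinct,
    uniformly chosen non-elite members of the offspring population.  Elites
    are immune to replacement and population size is conserved, so the
    returned population contains every elite and every preserved parent.

    ``slots`` optionally forces the replaced indices (in father-then-mother
    order per record) — used to reproduce worked examples deterministically.
    """
    pop = list(offspring)
    elite_ids = {id(rec.elite) for rec in elite_records}
    non_elite = [i for i, ind in enumerate(pop) if id(ind) not in elite_ids]
    inserts: list[Individual] = []
    for rec in elite_records:
        inserts.extend([rec.father, rec.mother])
    if len(inserts) > len(non_elite):
        raise ValueError(
            f"cannot insert {len(inserts)} preserved parents into "
            f"{len(non_elite)} non-elite slots"
        )
    if slots is None:
        chosen = rng.choice(len(non_elite), size=len(inserts), replace=False)
        slot_idx = [non_elite[i] for i in chosen]
    else:
        slot_idx = list(slots)
        if len(slot_idx) != len(inserts) or len(set(slot_idx)) != len(slot_idx):
            raise ValueError("slots must be distinct and one per preserved parent")
        if any(i not in non_elite for i in slot_idx):
            raise ValueError("cannot replace an elite")
    for i, parent in zip(slot_idx, inserts):
        pop[i] = parent
    return pop


def identify_elites(
    members: list[Individual], n_elites: int
) -> list[ElitistRecord]:
    """The ``n_elites`` lowest-energy members (stable tie-break) with their
    preserved parents; parentless individuals self-parent."""
    ranked = _sorted_by_energy(members)[:n_elites]
    records = []
    for elite in ranked:
        if elite.parents is None:
            records.append(ElitistRecord(elite, elite, elite))
        else:
            records.append(ElitistRecord(elite, elite.parents[0], elite.parents[1]))
    return records


def local_search(
    individual: Individual,
    cfg: SearchConfig,
    ctx: EvaluationContext,
    space: SearchSpace,
    rng: np.random.Generator,
) -> Individual:
    """Lamarckian Solis-Wets refinement.

    Adaptive random walk: propose ``x + d`` with ``d ~ N(0, rho)`` per gene;
    accept on strict energy decrease, otherwise try the opposite step
    ``x - d``.  The step size rho doubles after ``ls_success_limit``
    consecutive successes and halves after ``ls_failure_limit`` consecutive
    failures; the walk stops at ``ls_max_iter`` iterations, when rho falls
    below ``ls_rho_min``, or when the evaluation budget runs out.  The
    improved genome is written back (returned individual replaces the
    input), so the result's energy is never worse than the input's.
    """
    if cfg.ls_max_iter <= 0:
        return individual
    x = individual.genome.copy()
    fx = individual.energy
    if fx is None:
        fx = ctx.evaluate(x)

    fast = getattr(ctx.objective, "fast_local_search", None)
    if fast is not None and isinstance(space, PoseSpace):
        # compiled Solis-Wets walk; one RNG draw seeds it so the overall
        # run remains reproducible from the single generator
        budget = (
            ctx.max_evaluations - ctx.count
            if ctx.max_evaluations is not None
            else 2**62
        )
        if budget <= 0:
            return individual
        seed = int(rng.integers(2**31))
        x_new, fx_new, used = fast(
            x, fx, cfg.ls_rho0, cfg.ls_max_iter, cfg.ls_rho_min,
            cfg.ls_success_limit, cfg.ls_failure_limit, cfg.ls_expand,
            cfg.ls_contract, budget, seed, space.t_lower, space.t_upper,
        )
        ctx.register_batch(used, x_new, fx_new)
        if fx_new < fx:
            return Individual(genome=x_new, energy=float(fx_new),
                              parents=individual.parents)
        return individual

    rho = cfg.ls_rho0
    successes = failures = 0
    try:
        for _ in range(cfg.ls_max_iter):
            if rho < cfg.ls_rho_min:
                break
            d = rng.normal(0.0, rho, size=space.length)
            cand = space.repair(x + d)
            f_cand = ctx.evaluate(cand)
            if f_cand < fx:
                x, fx = cand, f_cand
                successes, failures = successes + 1, 0
            else:
                cand = space.repair(x - d)
                f_cand = ctx.evaluate(cand)
                if f_cand < fx:
                    x, fx = cand, f_cand
                    successes, failures = successes + 1, 0
                else:
                    successes, failures = 0, failures + 1
            if successes >= cfg.ls_success_limit:
                rho *= cfg.ls_expand
                successes = 0
            elif failures >= cfg.ls_failure_limit:
                rho *= cfg.ls_contract
                failures = 0
    except BudgetExhausted:
        pass
    if fx < (individual.energy if individual.energy is not None else math.inf):
        return Individual(genome=x, energy=fx, parents=individual.parents)
    return individual


# ---------------------------------------------------------------------------
# generational drivers


def _evaluate_all(members: list[Individual], ctx: EvaluationContext) -> None:
    for ind in members:
        if ind.energy is None:
            ind.energy = ctx.evaluate(ind.genome)


def _best(members: list[Individual]) -> Individual:
    return min(
        (m for m in members if m.energy is not None), key=lambda m: m.energy
    )


def _run(
    problem: Problem,
    config: SearchConfig,
    seed: int | None,
    use_cep: bool,
    use_ls: bool,
    algorithm: str,
) -> RunSummary:
    cfg = config
    seed = cfg.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    space = problem.space
    ctx = EvaluationContext(problem.objective, cfg.max_evaluations)

    pop = [Individual(space.random(rng)) for _ in range(cfg.pop_size)]
    best: Individual | None = None
    generation = 0
    try:
        _evaluate_all(pop, ctx)
        best = _best(pop).snapshot()
        for generation in range(1, cfg.max_generations + 1):
            # selection + crossover produce the offspring generation
            ranked = _sorted_by_energy(pop)
            probs = _rank_probabilities(len(ranked), cfg.selection_pressure)
            offspring: list[Individual] = []
            while len(offspring) < cfg.pop_size:
                ia, ib = rng.choice(len(ranked), size=2, p=probs)
                pa, pb = ranked[ia], ranked[ib]
                snap = (pa.snapshot(), pb.snapshot())
                if rng.random() < cfg.crossover_rate:
                    ga, gb = one_point_crossover(pa.genome, pb.genome, rng, space)
                    offspring.append(Individual(ga, parents=snap))
                    offspring.append(Individual(gb, parents=snap))
                else:
                    offspring.append(
                        Individual(pa.genome.copy(), pa.energy, parents=snap)
                    )
                    offspring.append(
                        Individual(pb.genome.copy(), pb.energy, parents=snap)
                    )
            offspring = offspring[: cfg.pop_size]
            _evaluate_all(offspring, ctx)

            elite_member_ids: set[int] = set()
            if use_cep:
                records = identify_elites(offspring, cfg.n_elites)
                offspring = cep_update(offspring, records, rng)
                elite_member_ids = {id(rec.elite) for rec in records}

            # real mutation on non-elite members (vectorized over the
            # population; per-gene semantics identical to real_mutation)
            rows = [
                i for i in range(cfg.pop_size)
                if id(offspring[i]) not in elite_member_ids
            ]
            if rows:
                mat = np.stack([offspring[i].genome for i in rows])
                new_mat, changed = space.mutate_batch(mat, cfg, rng)
                for r, i in enumerate(rows):
                    if changed[r]:
                        offspring[i] = Individual(
                            new_mat[r].copy(), parents=offspring[i].parents
                        )
            _evaluate_all(offspring, ctx)

            if use_ls and cfg.ls_frequency > 0:
                n_ls = max(1, round(cfg.ls_frequency * cfg.pop_size))
                chosen = rng.choice(cfg.pop_size, size=n_ls, replace=False)
                for i in chosen:
                    offspring[i] = local_search(offspring[i], cfg, ctx, space, rng)

            pop = offspring
            gen_best = _best(pop)
            if best is None or gen_best.energy < best.energy:
                best = gen_best.snapshot()
            if ctx.exhausted:
                break
    except BudgetExhausted:
        pass  # partial generation: the context still holds the best-so-far
    if ctx.best_vector is None:  # pragma: no cover - budget >= 1 guaranteed
        raise RuntimeError("no individual was ever evaluated")
    del best

    if use_ls and cfg.max_generations > 0 and not ctx.exhausted:
        # final Lamarckian polish: drive the best pose ever seen to its
        # local optimum before reporting it
        polish = Individual(ctx.best_vector.copy(), energy=ctx.best_energy)
        try:
            for _ in range(3):
                polish = local_search(polish, cfg, ctx, space, rng)
        except BudgetExhausted:
            pass

    best_rmsd = None
    if problem.topo is not None and problem.reference_coords is not None:
        coords = decode(Genome.from_vector(ctx.best_vector), problem.topo)
        best_rmsd = ligand_rmsd(problem.topo, coords, problem.reference_coords)
    return RunSummary(
        best_genome=ctx.best_vector,
        best_energy=float(ctx.best_energy),
        best_rmsd=best_rmsd,
        n_evaluations=ctx.count,
        n_generations=generation,
        trace=list(ctx.trace),
        seed=seed,
        algorithm=algorithm,
    )


def run_cepga(
    problem: Problem, config: SearchConfig | None = None, seed: int | None = None
) -> RunSummary:
    """Full algorithm: GA + crossover elitist preservation + Lamarckian
    local search."""
    return _run(problem, config or SearchConfig(), seed, True, True, "cepga")


def run_ga(
    problem: Problem,
    config: SearchConfig | None = None,
    seed: int | None = None,
    local_search_enabled: bool = False,
) -> RunSummary:
    """Baseline: identical generational loop with CEP disabled (and local
    search off by default), so the ablation isolates the CEP mechanism."""
    label = "ga+ls" if local_search_enabled else "ga"
    return _run(
        problem, config or SearchConfig(), seed, False, local_search_enabled, label
    )


def dock(
    topo: LigandTopology,
    receptor: ReceptorModel,
    params: EnergyModelParams | None = None,
    config: SearchConfig | None = None,
    seed: int | None = None,
    reference_coords: np.ndarray | None = None,
    algorithm: str = "cepga",
) -> RunSummary:
    """Dock a ligand into a receptor with the requested search algorithm
    (``cepga``, ``ga`` or ``ga+ls``); reports pose RMSD when a reference
    conformation is given."""
    problem = Problem.docking(topo, receptor, params, reference_coords)
    if algorithm == "cepga":
        return run_cepga(problem, config, seed)
    if algorithm in ("ga", "ga+ls"):
        return run_ga(problem, config, seed, local_search_enabled=algorithm == "ga+ls")
    raise ValueError(f"unknown algorithm {algorithm!r}")
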
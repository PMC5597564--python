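"""Semi-empirical pairwise scoring function.

The default objective is an AutoDock4-style free-energy estimate built from
direct pairwise summation (no grid maps):

    E = W_vdw  * sum_ij ( A_ij/r^12 - B_ij/r^6 )          12-6 dispersion/repulsion
      + W_hb   * sum_ij ( C_ij/r^12 - D_ij/r^10 )         12-10 hydrogen bonds
      + W_elec * sum_ij   q_i q_j / (eps(r) * r)          screened Coulomb
      + W_ds   * sum_ij ( S_i V_j + S_j V_i ) e^{-r^2/2s^2}  desolvation
      + W_tor  * T                                        torsional penalty
      + intra-ligand nonbonded terms (pairs >= 3 bonds apart whose distance
        can change under the torsions)

with the sigmoidal Mehler-Solmajer distance-dependent dielectric.  Pair
coefficients follow the usual construction from the per-type table:
``A = eps * R^12``, ``B = 2 eps R^6`` (minimum of depth eps at R) and
``C = 5 eps_hb R^12``, ``D = 6 eps_hb R^10`` for donor/acceptor pairs.
Pairs beyond the nonbonded cutoff contribute exactly zero; below the clash
radius the pair energy is clamped (value at the clash radius plus a linear
repulsive ramp), so no genome inside the search box ever scores NaN/Inf.

The weights ship with the published AutoDock 4.2 free-energy coefficients
for face validity; the scorer performs no grid interpolation and makes no
claim of bit-compatibility with AutoDock itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .pose import Genome, LigandTopology, ReceptorModel, decode

__all__ = [
    "AtomTypeParams",
    "EnergyModelParams",
    "EnergyBreakdown",
    "BoundScorer",
    "BudgetExhausted",
    "EvaluationContext",
    "score",
    "load_atom_type_table",
]

ELECTROSTATIC_CONSTANT = 332.06363  # kcal mol^-1 Å e^-2
DESOLVATION_SIGMA = 3.5  # Å, Gaussian width of the desolvation kernel
CHARGE_SOLVATION_FACTOR = 0.01097  # charge-dependent term of S_i


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-type nonbonded parameters (AutoDock conventions)."""

    rii: float  # Å, sum of like-pair vdW radii
    epsii: float  # kcal/mol well depth
    vol: float  # Å^3 solvation volume
    solpar: float  # solvation parameter
    hbond: str  # "D" donor hydrogen, "A" acceptor, "-" neither


def load_atom_type_table(path: str | Path | None = None) -> dict[str, AtomTypeParams]:
    """Read the whitespace atom-type parameter table (shipped default)."""
    if path is None:
        text = (
            resources.files("cepdock").joinpath("data/ad4_params.dat").read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, AtomTypeParams] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, rii, epsii, vol, solpar, hbond = line.split()
        table[name] = AtomTypeParams(
            float(rii), float(epsii), float(vol), float(solpar), hbond
        )
    return table


# published AutoDock 4.2 free-energy coefficients
_DEFAULT_WEIGHTS = dict(
    w_vdw=0.1662, w_hbond=0.1209, w_elec=0.1406, w_desolv=0.1322, w_tor=0.2983
)


@dataclass(frozen=True)
class EnergyModelParams:
    """Scoring-function parameters: per-type table, global weights, the
    dielectric model, the nonbonded cutoff and the clash clamp."""

    atom_types: dict[str, AtomTypeParams] = field(default_factory=load_atom_type_table)
    w_vdw: float = _DEFAULT_WEIGHTS["w_vdw"]
    w_hbond: float = _DEFAULT_WEIGHTS["w_hbond"]
    w_elec: float = _DEFAULT_WEIGHTS["w_elec"]
    w_desolv: float = _DEFAULT_WEIGHTS["w_desolv"]
    w_tor: float = _DEFAULT_WEIGHTS["w_tor"]
    hbond_r: float = 1.9  # Å, donor-acceptor 12-10 minimum distance
    hbond_eps: float = 5.0  # kcal/mol, 12-10 well depth
    # Mehler-Solmajer sigmoidal dielectric eps(r) = A + B / (1 + k e^{-l B r})
    diel_a: float = -8.5525
    diel_k: float = 7.7839
    diel_lambda: float = 0.003627
    diel_eps0: float = 78.4
    cutoff: float = 8.0  # Å nonbonded cutoff
    clash_radius: float = 0.5  # Å, pair energies clamped below this distance
    clash_slope: float = 100.0  # kcal/mol/Å linear ramp inside the clash radius
    clash_cap: float = 100.0  # kcal/mol ceiling per repulsive 12-6/12-10 pair

    def __post_init__(self) -> None:
        for name in ("w_vdw", "w_hbond", "w_elec", "w_desolv", "w_tor"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite weight {name}")
        if self.cutoff <= 0 or self.clash_radius <= 0:
            raise ValueError("cutoff and clash radius must be positive")

    def with_weights(self, **weights: float) -> "EnergyModelParams":
        """Copy with some of w_vdw/w_hbond/w_elec/w_desolv/w_tor replaced."""
        return replace(self, **weights)

    def dielectric(self, r: np.ndarray) -> np.ndarray:
        b = self.diel_eps0 - self.diel_a
        return self.diel_a + b / (
            1.0 + self.diel_k * np.exp(-self.diel_lambda * b * np.asarray(r))
        )

    def pair_vdw(self, type_i: str, type_j: str) -> tuple[float, float]:
        """12-6 coefficients (A, B) for a type pair (Lorentz-Berthelot mix)."""
        pi, pj = self.atom_types[type_i], self.atom_types[type_j]
        r = 0.5 * (pi.rii + pj.rii)
        eps = math.sqrt(pi.epsii * pj.epsii)
        return eps * r**12, 2.0 * eps * r**6

    def pair_hbond(self, type_i: str, type_j: str) -> tuple[float, float] | None:
        """12-10 coefficients (C, D) if the pair is donor-H/acceptor, else None."""
        hi, hj = self.atom_types[type_i].hbond, self.atom_types[type_j].hbond
        if {hi, hj} != {"D", "A"}:
            return None
        r, eps = self.hbond_r, self.hbond_eps
        return 5.0 * eps * r**12, 6.0 * eps * r**10


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components (kcal/mol-scaled scoring units).  vdw/hbond/elec/
    desolv are intermolecular; ``intramolecular`` lumps all intra-ligand
    nonbonded terms; total is their sum plus the torsional penalty."""

    vdw: float
    hbond: float
    elec: float
    desolv: float
    torsional_penalty: float
    intramolecular: float

    @property
    def total(self) -> float:
        return (
            self.vdw
            + self.hbond
            + self.elec
            + self.desolv
            + self.torsional_penalty
            + self.intramolecular
        )


def _solvation_s(params: EnergyModelParams, type_code: str, charge: float) -> float:
    return params.atom_types[type_code].solpar + CHARGE_SOLVATION_FACTOR * abs(charge)


def _bond_graph_distances(n: int, bonds) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    if not bonds:
        return np.full((n, n), np.inf)
    rows = [i for i, j in bonds] + [j for i, j in bonds]
    cols = [j for i, j in bonds] + [i for i, j in bonds]
    g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(g, method="D", unweighted=True)


def _rigid_fragments(topo: LigandTopology) -> np.ndarray:
    """Label atoms by rigid fragment: union of all bonds that are not
    rotatable-bond axes."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    axes = {frozenset((t.axis_a, t.axis_b)) for t in topo.torsion_nodes}
    rigid = [b for b in topo.bonds if frozenset(b) not in axes]
    n = topo.n_atoms
    if not rigid:
        return np.arange(n)
    rows = [i for i, j in rigid] + [j for i, j in rigid]
    cols = [j for i, j in rigid] + [i for i, j in rigid]
    g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return connected_components(g, directed=False)[1]


class BoundScorer:
    """Scoring function bound to one (ligand topology, receptor, params)
    triple, with all pair coefficient matrices precomputed so repeated calls
    reduce to a handful of vectorized array operations."""

    def __init__(
        self,
        topo: LigandTopology,
        receptor: ReceptorModel,
        params: EnergyModelParams | None = None,
    ):
        self.topo = topo
        self.receptor = receptor
        self.params = params = params or EnergyModelParams()

        lig_types = [a.type_code for a in topo.atoms]
        rec_types = [a.type_code for a in receptor.atoms]
        for t in set(lig_types) | set(rec_types):
            if t not in params.atom_types:
                raise KeyError(f"unknown atom type {t!r}")
        lig_q = np.array([a.charge for a in topo.atoms])
        rec_q = np.array([a.charge for a in receptor.atoms])

        nl = topo.n_atoms
        self._inter = self._build_tables(lig_types, lig_q, rec_types, rec_q)
        self.rec_coords = receptor.coords()

        # intra-ligand pairs: AutoDock's exclusion rule (1-2, 1-3 and 1-4
        # interactions dropped, i.e. >= 4 bonds apart) and only pairs whose
        # distance can change under the torsions (different rigid fragments)
        dist = _bond_graph_distances(nl, topo.bonds)
        frag = _rigid_fragments(topo)
        ii, jj = [], []
        for i in range(nl):
            for j in range(i + 1, nl):
                if dist[i, j] >= 4 and frag[i] != frag[j]:
                    ii.append(i)
                    jj.append(j)
        self._intra_idx = (np.array(ii, dtype=int), np.array(jj, dtype=int))
        if ii:
            t_i = [lig_types[i] for i in ii]
            t_j = [lig_types[j] for j in jj]
            q_i = lig_q[self._intra_idx[0]]
            q_j = lig_q[self._intra_idx[1]]
            self._intra = self._build_tables(t_i, q_i, t_j, q_j, paired=True)
        else:
            self._intra = None

        t = topo.torsdof if topo.torsdof is not None else topo.n_torsions
        self.torsional_penalty = params.w_tor * t

    def _build_tables(self, types_i, q_i, types_j, q_j, paired: bool = False):
        """Pair coefficient arrays; full (ni x nj) outer tables, or aligned
        1-D arrays when ``paired``."""
        p = self.params
        ti = np.asarray(types_i)
        tj = np.asarray(types_j)
        if paired:
            pairs = list(zip(types_i, types_j))
        else:
            pairs = [(a, b) for a in types_i for b in types_j]
        A = np.empty(len(pairs))
        B = np.empty(len(pairs))
        C = np.zeros(len(pairs))
        D = np.zeros(len(pairs))
        hb = np.zeros(len(pairs), dtype=bool)
        S = np.empty(len(pairs))
        for k, (a, b) in enumerate(pairs):
            A[k], B[k] = p.pair_vdw(a, b)
            cd = p.pair_hbond(a, b)
            if cd is not None:
                C[k], D[k] = cd
                hb[k] = True
        if paired:
            qq = np.asarray(q_i) * np.asarray(q_j)
            vi = np.array([p.atom_types[a].vol for a in types_i])
            vj = np.array([p.atom_types[b].vol for b in types_j])
            si = np.array(
                [_solvation_s(p, a, q) for a, q in zip(types_i, q_i)]
            )
            sj = np.array(
                [_solvation_s(p, b, q) for b, q in zip(types_j, q_j)]
            )
            solv = si * vj + sj * vi
            shape = (len(types_i),)
        else:
            qq = np.outer(q_i, q_j).ravel()
            vi = np.array([p.atom_types[a].vol for a in types_i])
            vj = np.array([p.atom_types[b].vol for b in types_j])
            si = np.array([_solvation_s(p, a, q) for a, q in zip(types_i, q_i)])
            sj = np.array([_solvation_s(p, b, q) for b, q in zip(types_j, q_j)])
            solv = (np.outer(si, vj) + np.outer(vi, sj)).ravel()
            shape = (len(types_i), len(types_j))
        del ti, tj
        return dict(
            A=A, B=B, C=C, D=D, hb=hb, not_hb=(~hb).astype(float),
            qq=qq, solv=solv, shape=shape,
        )

    def _pair_terms(self, r: np.ndarray, tab) -> tuple[float, float, float, float]:
        """Summed (vdw, hbond, elec, desolv) for flat distance array ``r``
        against flat coefficient tables, applying cutoff and clash clamp."""
        p = self.params
        within = (r <= p.cutoff).astype(float)
        # pairs beyond the cutoff contribute exactly zero to every term
        ramp = np.maximum(p.clash_radius - r, 0.0) * p.clash_slope
        re = np.maximum(r, p.clash_radius)

        inv2 = 1.0 / (re * re)
        inv6 = inv2 * inv2 * inv2
        inv10 = inv6 * inv2 * inv2
        inv12 = inv6 * inv6
        not_hb = tab["not_hb"]
        # steric repulsion capped so clashes stay steep but finite: search
        # can rank clashing poses instead of drowning in 1/r^12 noise
        cap = p.clash_cap
        vdw_pair = (
            np.minimum(tab["A"] * inv12 - tab["B"] * inv6, cap) * not_hb + ramp
        )
        hb_pair = np.minimum(tab["C"] * inv12 - tab["D"] * inv10, cap)
        elec_pair = ELECTROSTATIC_CONSTANT * tab["qq"] / (p.dielectric(re) * re)
        ds_pair = tab["solv"] * np.exp(-(re * re) / (2.0 * DESOLVATION_SIGMA**2))

        vdw = p.w_vdw * float(vdw_pair @ within)
        hbond = p.w_hbond * float(hb_pair @ within)
        elec = p.w_elec * float(elec_pair @ within)
        desolv = p.w_desolv * float(ds_pair @ within)
        return vdw, hbond, elec, desolv

    def breakdown(self, coords: np.ndarray) -> EnergyBreakdown:
        coords = np.asarray(coords, dtype=float)
        if self.receptor.n_atoms:
            r = cdist(coords, self.rec_coords).ravel()
            vdw, hbond, elec, desolv = self._pair_terms(r, self._inter)
        else:
            vdw = hbond = elec = desolv = 0.0
        intra = 0.0
        if self._intra is not None:
            ii, jj = self._intra_idx
            ri = np.sqrt(np.sum((coords[ii] - coords[jj]) ** 2, axis=-1))
            intra = sum(self._pair_terms(ri, self._intra))
        return EnergyBreakdown(
            vdw=vdw,
            hbond=hbond,
            elec=elec,
            desolv=desolv,
            torsional_penalty=self.torsional_penalty,
            intramolecular=intra,
        )

    def __call__(self, coords: np.ndarray) -> float:
        return self.breakdown(coords).total


def score(
    coords: np.ndarray,
    topo: LigandTopology,
    receptor: ReceptorModel,
    params: EnergyModelParams | None = None,
) -> EnergyBreakdown:
    """One-shot scoring of decoded ligand coordinates.

    For repeated evaluation of the same system use :class:`BoundScorer`
    (identical result, precomputed coefficients).
    """
    return BoundScorer(topo, receptor, params).breakdown(coords)


# ---------------------------------------------------------------------------
# evaluation bookkeeping


class BudgetExhausted(RuntimeError):
    """Raised when an evaluation is requested past ``max_evaluations``."""


class EvaluationContext:
    """Counts objective evaluations against a budget and records the
    best-so-far trace at every strict improvement.

    ``evaluate`` increments the counter exactly once per actual objective
    computation; callers that cache energies simply do not call it again for
    a cached genome.
    """

    def __init__(self, objective, max_evaluations: int | None = None):
        self.objective = objective
        self.max_evaluations = max_evaluations
        self.count = 0
        self.best_energy = math.inf
        self.best_vector: np.ndarray | None = None
        self.trace: list[tuple[int, float]] = []  # (n_evaluations, best_energy)

    @property
    def exhausted(self) -> bool:
        return (
            self.max_evaluations is not None and self.count >= self.max_evaluations
        )

    def evaluate(self, vector: np.ndarray) -> float:
        if self.exhausted:
            raise BudgetExhausted(
                f"evaluation budget of {self.max_evaluations} exhausted"
            )
        energy = float(self.objective(vector))
        self.count += 1
        if energy < self.best_energy:
            self.best_energy = energy
            self.best_vector = np.array(vector, dtype=float, copy=True)
            self.trace.append((self.count, energy))
        return energy

    def register_batch(self, n_evals: int, vector: np.ndarray, energy: float) -> None:
        """Account for evaluations performed inside a compiled refinement
        block: bump the counter and record the block's best outcome."""
        self.count += int(n_evals)
        if energy < self.best_energy:
            self.best_energy = float(energy)
            self.best_vector = np.array(vector, dtype=float, copy=True)
            self.trace.append((self.count, float(energy)))


def make_docking_objective(
    topo: LigandTopology,
    receptor: ReceptorModel,
    params: EnergyModelParams | None = None,
    compiled: bool = True,
):
    """Genome-vector objective: decode then score (total energy).

    Uses the numba-compiled fused kernel when available (numerically
    identical to the numpy path; equality is asserted in the test suite);
    pass ``compiled=False`` to force the reference implementation.
    """
    scorer = BoundScorer(topo, receptor, params)
    if compiled:
        try:
            from ._fastpath import build_fast_objective

            return build_fast_objective(scorer)
        except ImportError:  # pragma: no cover - numba is a hard dependency
            pass

    def objective(vector: np.ndarray) -> float:
        return scorer(decode(vector, topo))

    objective.scorer = scorer  # type: ignore[attr-defined]
    return objective
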
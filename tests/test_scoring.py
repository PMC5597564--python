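"""Scoring function: closed forms, oracle equivalence, evaluation accounting."""

import math

import numpy as np
import pytest

from cepdock import (
    Atom,
    BoundScorer,
    BudgetExhausted,
    EnergyModelParams,
    EvaluationContext,
    LigandTopology,
    ReceptorModel,
    score,
)
from cepdock.scoring import (
    CHARGE_SOLVATION_FACTOR,
    DESOLVATION_SIGMA,
    ELECTROSTATIC_CONSTANT,
)
from cepdock.synthetic import FixtureSpec, make_fixture


def _single_pair(r, lig_type="C", rec_type="C", lig_q=0.0, rec_q=0.0):
    topo = LigandTopology(
        atoms=(Atom(0, lig_type[0], lig_type, (0.0, 0.0, 0.0), lig_q),), bonds=()
    )
    rec = ReceptorModel(
        atoms=(Atom(0, rec_type[0], rec_type, (r, 0.0, 0.0), rec_q),),
        bounding_box=((0, 0, 0), (10, 10, 10)),
    )
    return topo, rec


def naive_energy(coords, topo, receptor, params):
    """Independent oracle: plain double-loop pair summation following the
    published functional form, no vectorization, no shared code paths."""
    coords = np.asarray(coords, dtype=float)
    rec = [(a.type_code, a.charge, np.asarray(a.coords)) for a in receptor.atoms]
    lig = [(a.type_code, a.charge) for a in topo.atoms]

    def pair(t1, q1, t2, q2, r):
        if r > params.cutoff:
            return 0.0, 0.0, 0.0, 0.0
        ramp = params.clash_slope * max(params.clash_radius - r, 0.0)
        r = max(r, params.clash_radius)
        cd = params.pair_hbond(t1, t2)
        if cd is None:
            a_, b_ = params.pair_vdw(t1, t2)
            vdw = min(a_ / r**12 - b_ / r**6, params.clash_cap) + ramp
            hb = 0.0
        else:
            c_, d_ = cd
            vdw = ramp
            hb = min(c_ / r**12 - d_ / r**10, params.clash_cap)
        eps = float(params.dielectric(r))
        elec = ELECTROSTATIC_CONSTANT * q1 * q2 / (eps * r)
        s1 = params.atom_types[t1].solpar + CHARGE_SOLVATION_FACTOR * abs(q1)
        s2 = params.atom_types[t2].solpar + CHARGE_SOLVATION_FACTOR * abs(q2)
        v1, v2 = params.atom_types[t1].vol, params.atom_types[t2].vol
        ds = (s1 * v2 + s2 * v1) * math.exp(-(r * r) / (2 * DESOLVATION_SIGMA**2))
        return vdw, hb, elec, ds

    vdw = hb = elec = ds = 0.0
    for i, (t1, q1) in enumerate(lig):
        for t2, q2, pos in rec:
            terms = pair(t1, q1, t2, q2, float(np.linalg.norm(coords[i] - pos)))
            vdw, hb, elec, ds = (
                vdw + terms[0],
                hb + terms[1],
                elec + terms[2],
                ds + terms[3],
            )
    total = (
        params.w_vdw * vdw
        + params.w_hbond * hb
        + params.w_elec * elec
        + params.w_desolv * ds
    )
    # intra-ligand terms through the same pair function
    scorer = BoundScorer(topo, receptor, params)
    ii, jj = scorer._intra_idx
    intra = 0.0
    for i, j in zip(ii, jj):
        t1, q1 = lig[i]
        t2, q2 = lig[j]
        terms = pair(t1, q1, t2, q2, float(np.linalg.norm(coords[i] - coords[j])))
        intra += (
            params.w_vdw * terms[0]
            + params.w_hbond * terms[1]
            + params.w_elec * terms[2]
            + params.w_desolv * terms[3]
        )
    t = topo.torsdof if topo.torsdof is not None else topo.n_torsions
    return total + intra + params.w_tor * t


class TestClosedForms:
    def test_lj_minimum_location_and_depth(self, params):
        """Pure 12-6 pair: minimum at r* = (2A/B)^(1/6) with energy
        -W_vdw * B^2 / (4A)."""
        p = params.with_weights(w_hbond=0.0, w_elec=0.0, w_desolv=0.0, w_tor=0.0)
        a_, b_ = p.pair_vdw("C", "C")
        r_star = (2.0 * a_ / b_) ** (1.0 / 6.0)
        topo, rec = _single_pair(r_star)
        e_min = score(topo.template_coords, topo, rec, p).total
        assert e_min == pytest.approx(-p.w_vdw * b_**2 / (4.0 * a_), abs=1e-9)
        # nearby distances score strictly higher
        for dr in (-0.1, 0.1):
            topo2, rec2 = _single_pair(r_star + dr)
            assert score(topo2.template_coords, topo2, rec2, p).total > e_min

    def test_beyond_cutoff_only_torsional_penalty(self, params):
        topo, rec = _single_pair(params.cutoff + 5.0, lig_q=0.5, rec_q=-0.5)
        bd = score(topo.template_coords, topo, rec, params)
        assert bd.total == pytest.approx(params.w_tor * 0)
        assert bd.vdw == bd.hbond == bd.elec == bd.desolv == 0.0

    def test_two_by_two_hand_sum(self, params):
        """Toy 2x2 system matches an independent double-loop summation."""
        topo = LigandTopology(
            atoms=(
                Atom(0, "C", "C", (0.0, 0.0, 0.0), 0.2),
                Atom(1, "O", "OA", (1.5, 0.0, 0.0), -0.3),
            ),
            bonds=((0, 1),),
        )
        rec = ReceptorModel(
            atoms=(
                Atom(0, "H", "HD", (0.0, 2.0, 0.0), 0.2),
                Atom(1, "C", "C", (3.0, 1.0, 1.0), -0.1),
            ),
            bounding_box=((0, 0, 0), (10, 10, 10)),
        )
        total = score(topo.template_coords, topo, rec, params).total
        expected = naive_energy(topo.template_coords, topo, rec, params)
        assert total == pytest.approx(expected, abs=1e-9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vectorized_equals_naive_on_random_system(self, seed, params):
        rng = np.random.default_rng(seed)
        types = ["C", "OA", "N", "HD", "A"]

        def spread_points(n, lo, hi, min_sep=1.8):
            pts: list[np.ndarray] = []
            while len(pts) < n:
                cand = rng.uniform(lo, hi, 3)
                if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
                    pts.append(cand)
            return pts

        lig_pts = spread_points(25, -4, 4)
        lig_atoms = tuple(
            Atom(
                i,
                "X",
                str(rng.choice(types)),
                tuple(lig_pts[i]),
                float(rng.uniform(-0.5, 0.5)),
            )
            for i in range(25)
        )
        # chain bonds so some intra pairs exist (no torsions: intra empty,
        # exercised separately via fixtures)
        topo = LigandTopology(
            atoms=lig_atoms, bonds=tuple((i, i + 1) for i in range(24))
        )
        rec_pts = spread_points(25, -6, 6)
        rec_atoms = tuple(
            Atom(
                i,
                "X",
                str(rng.choice(types)),
                tuple(rec_pts[i]),
                float(rng.uniform(-0.5, 0.5)),
            )
            for i in range(25)
        )
        rec = ReceptorModel(atoms=rec_atoms, bounding_box=((0, 0, 0), (10, 10, 10)))
        coords = topo.template_coords
        assert score(coords, topo, rec, params).total == pytest.approx(
            naive_energy(coords, topo, rec, params), rel=1e-12, abs=1e-9
        )

    def test_intra_terms_match_naive_on_flexible_ligand(self, params):
        fx = make_fixture(FixtureSpec(n_torsions=3, rng_seed=4), quality_control=False)
        coords = fx.reference_coords
        assert score(coords, fx.topo, fx.receptor, params).total == pytest.approx(
            naive_energy(coords, fx.topo, fx.receptor, params), abs=1e-9
        )


class TestInvariances:
    def test_receptor_atom_beyond_cutoff_changes_nothing(self, params):
        fx = make_fixture(FixtureSpec(n_torsions=1, rng_seed=2), quality_control=False)
        base = score(fx.reference_coords, fx.topo, fx.receptor, params).total
        far = Atom(
            fx.receptor.n_atoms, "C", "C", (100.0, 100.0, 100.0), 0.3
        )
        rec2 = ReceptorModel(
            atoms=fx.receptor.atoms + (far,), bounding_box=fx.receptor.bounding_box
        )
        assert score(fx.reference_coords, fx.topo, rec2, params).total == base

    def test_receptor_permutation_invariance(self, params):
        fx = make_fixture(FixtureSpec(n_torsions=2, rng_seed=6), quality_control=False)
        perm = np.random.default_rng(0).permutation(fx.receptor.n_atoms)
        shuffled = ReceptorModel(
            atoms=tuple(
                Atom(k, a.element, a.type_code, a.coords, a.charge)
                for k, a in enumerate(fx.receptor.atoms[i] for i in perm)
            ),
            bounding_box=fx.receptor.bounding_box,
        )
        a = score(fx.reference_coords, fx.topo, fx.receptor, params).total
        b = score(fx.reference_coords, fx.topo, shuffled, params).total
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_nan_inside_search_box(self, fixture_t2):
        prob = fixture_t2.problem()
        rng = np.random.default_rng(1)
        vals = [prob.objective(prob.space.random(rng)) for _ in range(300)]
        assert np.all(np.isfinite(vals))

    def test_breakdown_total_is_component_sum(self, fixture_t2, params):
        bd = score(
            fixture_t2.reference_coords, fixture_t2.topo, fixture_t2.receptor, params
        )
        parts = (
            bd.vdw + bd.hbond + bd.elec + bd.desolv + bd.torsional_penalty
            + bd.intramolecular
        )
        assert bd.total == pytest.approx(parts, abs=1e-9)

    def test_overlapping_atoms_clamped_finite(self, params):
        topo, rec = _single_pair(0.001)
        assert math.isfinite(score(topo.template_coords, topo, rec, params).total)


class TestEvaluationContext:
    def test_counter_and_determinism(self, fixture_t2):
        prob = fixture_t2.problem()
        ctx = EvaluationContext(prob.objective)
        vec = prob.space.random(np.random.default_rng(0))
        e1, e2 = ctx.evaluate(vec), ctx.evaluate(vec)
        assert e1 == e2
        assert ctx.count == 2

    def test_budget_signal_on_excess_call(self, fixture_t2):
        prob = fixture_t2.problem()
        ctx = EvaluationContext(prob.objective, max_evaluations=10)
        rng = np.random.default_rng(0)
        for _ in range(10):
            ctx.evaluate(prob.space.random(rng))
        with pytest.raises(BudgetExhausted):
            ctx.evaluate(prob.space.random(rng))
        assert ctx.count == 10

    def test_trace_records_strict_improvements(self, fixture_t2):
        prob = fixture_t2.problem()
        ctx = EvaluationContext(prob.objective)
        rng = np.random.default_rng(3)
        for _ in range(200):
            ctx.evaluate(prob.space.random(rng))
        energies = [e for _, e in ctx.trace]
        counts = [n for n, _ in ctx.trace]
        assert all(b < a for a, b in zip(energies, energies[1:]))
        assert all(b > a for a, b in zip(counts, counts[1:]))
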
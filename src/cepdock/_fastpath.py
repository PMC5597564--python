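"""Numba-compiled genome-to-energy kernel.

Single fused routine: decode the genome (torsions depth-first, quaternion
about the root centroid, translation) and sum the pairwise energy model.
Numerically identical to the pure-numpy path in :mod:`cepdock.scoring`
(asserted by the test suite); exists purely so generational searches with
tens of thousands of evaluations run in seconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["build_fast_objective"]


@njit(cache=True)
def _dock_energy(
    vec,
    template,
    pivot,
    axis_a,
    axis_b,
    moved_flat,
    moved_off,
    rec_xyz,
    inter_A,
    inter_B,
    inter_C,
    inter_D,
    inter_hb,
    inter_qq,
    inter_solv,
    intra_i,
    intra_j,
    intra_A,
    intra_B,
    intra_C,
    intra_D,
    intra_hb,
    intra_qq,
    intra_solv,
    tor_pen,
    w_vdw,
    w_hbond,
    w_elec,
    w_desolv,
    cutoff,
    clash_radius,
    clash_slope,
    clash_cap,
    diel_a,
    diel_b,
    diel_k,
    diel_lb,
    desolv_inv2s2,
    elec_const,
):
    n = template.shape[0]
    coords = template.copy()

    # torsions, root-outward
    n_tor = axis_a.shape[0]
    for t in range(n_tor):
        angle = vec[7 + t]
        if angle == 0.0:
            continue
        a = axis_a[t]
        b = axis_b[t]
        kx = coords[b, 0] - coords[a, 0]
        ky = coords[b, 1] - coords[a, 1]
        kz = coords[b, 2] - coords[a, 2]
        norm = math.sqrt(kx * kx + ky * ky + kz * kz)
        kx /= norm
        ky /= norm
        kz /= norm
        c = math.cos(angle)
        s = math.sin(angle)
        for m in range(moved_off[t], moved_off[t + 1]):
            i = moved_flat[m]
            vx = coords[i, 0] - coords[a, 0]
            vy = coords[i, 1] - coords[a, 1]
            vz = coords[i, 2] - coords[a, 2]
            dot = vx * kx + vy * ky + vz * kz
            cx = ky * vz - kz * vy
            cy = kz * vx - kx * vz
            cz = kx * vy - ky * vx
            coords[i, 0] = coords[a, 0] + vx * c + cx * s + kx * dot * (1.0 - c)
            coords[i, 1] = coords[a, 1] + vy * c + cy * s + ky * dot * (1.0 - c)
            coords[i, 2] = coords[a, 2] + vz * c + cz * s + kz * dot * (1.0 - c)

    # rigid body: quaternion about the root centroid, then translation
    qw, qx, qy, qz = vec[3], vec[4], vec[5], vec[6]
    qn = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
    qw /= qn
    qx /= qn
    qy /= qn
    qz /= qn
    r00 = 1.0 - 2.0 * (qy * qy + qz * qz)
    r01 = 2.0 * (qx * qy - qw * qz)
    r02 = 2.0 * (qx * qz + qw * qy)
    r10 = 2.0 * (qx * qy + qw * qz)
    r11 = 1.0 - 2.0 * (qx * qx + qz * qz)
    r12 = 2.0 * (qy * qz - qw * qx)
    r20 = 2.0 * (qx * qz - qw * qy)
    r21 = 2.0 * (qy * qz + qw * qx)
    r22 = 1.0 - 2.0 * (qx * qx + qy * qy)
    for i in range(n):
        vx = coords[i, 0] - pivot[0]
        vy = coords[i, 1] - pivot[1]
        vz = coords[i, 2] - pivot[2]
        coords[i, 0] = r00 * vx + r01 * vy + r02 * vz + pivot[0] + vec[0]
        coords[i, 1] = r10 * vx + r11 * vy + r12 * vz + pivot[1] + vec[1]
        coords[i, 2] = r20 * vx + r21 * vy + r22 * vz + pivot[2] + vec[2]

    total = tor_pen

    # intermolecular pairs
    nr = rec_xyz.shape[0]
    for i in range(n):
        for j in range(nr):
            dx = coords[i, 0] - rec_xyz[j, 0]
            dy = coords[i, 1] - rec_xyz[j, 1]
            dz = coords[i, 2] - rec_xyz[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > cutoff:
                continue
            k = i * nr + j
            ramp = 0.0
            if r < clash_radius:
                ramp = clash_slope * (clash_radius - r)
                r = clash_radius
            inv2 = 1.0 / (r * r)
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            if inter_hb[k]:
                e = inter_C[k] * inv12 - inter_D[k] * inv6 * inv2 * inv2
                if e > clash_cap:
                    e = clash_cap
                total += w_hbond * e + w_vdw * ramp
            else:
                e = inter_A[k] * inv12 - inter_B[k] * inv6
                if e > clash_cap:
                    e = clash_cap
                total += w_vdw * (e + ramp)
            eps = diel_a + diel_b / (
                1.0 + diel_k * math.exp(-diel_lb * r)
            )
            total += w_elec * elec_const * inter_qq[k] / (eps * r)
            total += w_desolv * inter_solv[k] * math.exp(-(r * r) * desolv_inv2s2)

    # intra-ligand pairs
    for k in range(intra_i.shape[0]):
        i = intra_i[k]
        j = intra_j[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > cutoff:
            continue
        ramp = 0.0
        if r < clash_radius:
            ramp = clash_slope * (clash_radius - r)
            r = clash_radius
        inv2 = 1.0 / (r * r)
        inv6 = inv2 * inv2 * inv2
        inv12 = inv6 * inv6
        if intra_hb[k]:
            e = intra_C[k] * inv12 - intra_D[k] * inv6 * inv2 * inv2
            if e > clash_cap:
                e = clash_cap
            total += w_hbond * e + w_vdw * ramp
        else:
            e = intra_A[k] * inv12 - intra_B[k] * inv6
            if e > clash_cap:
                e = clash_cap
            total += w_vdw * (e + ramp)
        eps = diel_a + diel_b / (1.0 + diel_k * math.exp(-diel_lb * r))
        total += w_elec * elec_const * intra_qq[k] / (eps * r)
        total += w_desolv * intra_solv[k] * math.exp(-(r * r) * desolv_inv2s2)

    return total


def build_fast_objective(scorer):
    """Closure over a :class:`cepdock.scoring.BoundScorer`'s precomputed
    tables; returns vector -> total energy."""
    from .scoring import (
        DESOLVATION_SIGMA,
        ELECTROSTATIC_CONSTANT,
    )

    topo = scorer.topo
    p = scorer.params
    template = np.ascontiguousarray(topo._template)
    pivot = np.ascontiguousarray(topo.root_centroid)
    axis_a = np.array([t.axis_a for t in topo.torsion_nodes], dtype=np.int64)
    axis_b = np.array([t.axis_b for t in topo.torsion_nodes], dtype=np.int64)
    moved_arrays = topo._moved_index_arrays
    moved_flat = (
        np.concatenate(moved_arrays).astype(np.int64)
        if moved_arrays
        else np.empty(0, dtype=np.int64)
    )
    moved_off = np.zeros(len(moved_arrays) + 1, dtype=np.int64)
    for t, arr in enumerate(moved_arrays):
        moved_off[t + 1] = moved_off[t] + arr.size

    rec_xyz = np.ascontiguousarray(scorer.rec_coords.reshape(-1, 3))
    it = scorer._inter
    if scorer._intra is not None:
        ii = scorer._intra_idx[0].astype(np.int64)
        jj = scorer._intra_idx[1].astype(np.int64)
        ia = scorer._intra
        intra = (
            ia["A"], ia["B"], ia["C"], ia["D"], ia["hb"], ia["qq"], ia["solv"],
        )
    else:
        ii = jj = np.empty(0, dtype=np.int64)
        z = np.empty(0, dtype=float)
        intra = (z, z, z, z, np.empty(0, dtype=np.bool_), z, z)

    args = (
        template,
        pivot,
        axis_a,
        axis_b,
        moved_flat,
        moved_off,
        rec_xyz,
        it["A"], it["B"], it["C"], it["D"], it["hb"], it["qq"], it["solv"],
        ii, jj, *intra,
        scorer.torsional_penalty,
        p.w_vdw, p.w_hbond, p.w_elec, p.w_desolv,
        p.cutoff, p.clash_radius, p.clash_slope, p.clash_cap,
        p.diel_a, p.diel_eps0 - p.diel_a, p.diel_k,
        p.diel_lambda * (p.diel_eps0 - p.diel_a),
        1.0 / (2.0 * DESOLVATION_SIGMA**2),
        ELECTROSTATIC_CONSTANT,
    )

    def objective(vec: np.ndarray) -> float:
        return float(_dock_energy(np.ascontiguousarray(vec, dtype=np.float64), *args))

    def fast_local_search(
        x, fx, rho, max_iter, rho_min, succ_lim, fail_lim, expand, contract,
        budget, seed, t_lower, t_upper,
    ):
        return _solis_wets(
            np.ascontiguousarray(x, dtype=np.float64), fx, rho, max_iter,
            rho_min, succ_lim, fail_lim, expand, contract, budget, seed,
            np.ascontiguousarray(t_lower), np.ascontiguousarray(t_upper),
            *args,
        )

    objective.scorer = scorer  # type: ignore[attr-defined]
    objective.fast_local_search = fast_local_search  # type: ignore[attr-defined]
    return objective


@njit(cache=True)
def _repair_pose(x, t_lower, t_upper):
    for i in range(3):
        if x[i] < t_lower[i]:
            x[i] = t_lower[i]
        elif x[i] > t_upper[i]:
            x[i] = t_upper[i]
    qn = math.sqrt(x[3] * x[3] + x[4] * x[4] + x[5] * x[5] + x[6] * x[6])
    if qn > 0.0:
        for i in range(3, 7):
            x[i] /= qn
    else:
        x[3] = 1.0
        x[4] = x[5] = x[6] = 0.0
    for i in range(7, x.size):
        w = -((-x[i] + math.pi) % (2.0 * math.pi) - math.pi)
        x[i] = w
    return x


@njit(cache=True)
def _solis_wets(
    x0,
    f0,
    rho,
    max_iter,
    rho_min,
    succ_lim,
    fail_lim,
    expand,
    contract,
    budget,
    seed,
    t_lower,
    t_upper,
    # dock-energy arguments follow
    template,
    pivot,
    axis_a,
    axis_b,
    moved_flat,
    moved_off,
    rec_xyz,
    inter_A,
    inter_B,
    inter_C,
    inter_D,
    inter_hb,
    inter_qq,
    inter_solv,
    intra_i,
    intra_j,
    intra_A,
    intra_B,
    intra_C,
    intra_D,
    intra_hb,
    intra_qq,
    intra_solv,
    tor_pen,
    w_vdw,
    w_hbond,
    w_elec,
    w_desolv,
    cutoff,
    clash_radius,
    clash_slope,
    clash_cap,
    diel_a,
    diel_b,
    diel_k,
    diel_lb,
    desolv_inv2s2,
    elec_const,
):
    """Adaptive random-walk refinement with strict-decrease acceptance and
    opposite-step testing, entirely inside compiled code.  Returns the
    refined genome, its energy and the number of evaluations consumed."""
    np.random.seed(seed)
    n = x0.size
    x = x0.copy()
    fx = f0
    evals = 0
    successes = 0
    failures = 0
    for _ in range(max_iter):
        if rho < rho_min or evals >= budget:
            break
        d = np.empty(n)
        for i in range(n):
            d[i] = np.random.normal(0.0, rho)
        cand = _repair_pose(x + d, t_lower, t_upper)
        f = _dock_energy(
            cand, template, pivot, axis_a, axis_b, moved_flat, moved_off,
            rec_xyz, inter_A, inter_B, inter_C, inter_D, inter_hb, inter_qq,
            inter_solv, intra_i, intra_j, intra_A, intra_B, intra_C, intra_D,
            intra_hb, intra_qq, intra_solv, tor_pen, w_vdw, w_hbond, w_elec,
            w_desolv, cutoff, clash_radius, clash_slope, clash_cap, diel_a,
            diel_b, diel_k, diel_lb, desolv_inv2s2, elec_const,
        )
        evals += 1
        accepted = False
        if f < fx:
            x = cand
            fx = f
            accepted = True
        elif evals < budget:
            cand = _repair_pose(x - d, t_lower, t_upper)
            f = _dock_energy(
                cand, template, pivot, axis_a, axis_b, moved_flat, moved_off,
                rec_xyz, inter_A, inter_B, inter_C, inter_D, inter_hb,
                inter_qq, inter_solv, intra_i, intra_j, intra_A, intra_B,
                intra_C, intra_D, intra_hb, intra_qq, intra_solv, tor_pen,
                w_vdw, w_hbond, w_elec, w_desolv, cutoff, clash_radius,
                clash_slope, clash_cap, diel_a, diel_b, diel_k, diel_lb,
                desolv_inv2s2, elec_const,
            )
            evals += 1
            if f < fx:
                x = cand
                fx = f
                accepted = True
        if accepted:
            successes += 1
            failures = 0
            if successes >= succ_lim:
                rho *= expand
                successes = 0
        else:
            failures += 1
            successes = 0
            if failures >= fail_lim:
                rho *= contract
                failures = 0
    return x, fx, evals
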
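"""Numba-compiled inner loops for the discrete gene-circuit update.

The circuit state update is

    y[t+1] = (dt/tau) * sigmoid(W @ y[t] + B) + (1 - dt/tau) * y[t]

which is a convex combination of the current state and a sigmoid drive as
long as dt/tau <= 1, so trajectories started in (0,1)^n stay there.  The
kernels below add, in a fixed per-step order: state update -> scheduled
displacement events (noise kicks / pushes) -> wall projection in a 2-D
plane -> clamp overwrite.
"""

import numpy as np
from numba import njit

__all__ = [
    "gene_circuit_rollout",
    "gene_circuit_rollout_perturbed",
    "gene_circuit_loss_grad",
]


@njit(cache=True)
def _sigmoid(x):
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        v = x[i]
        if v >= 0.0:
            out[i] = 1.0 / (1.0 + np.exp(-v))
        else:
            e = np.exp(v)
            out[i] = e / (1.0 + e)
    return out


@njit(cache=True)
def _step_inplace(W, B, a, y, scratch):
    n = y.shape[0]
    for i in range(n):
        u = B[i]
        for j in range(n):
            u += W[i, j] * y[j]
        if u >= 0.0:
            s = 1.0 / (1.0 + np.exp(-u))
        else:
            e = np.exp(u)
            s = e / (1.0 + e)
        scratch[i] = a[i] * s + (1.0 - a[i]) * y[i]
    for i in range(n):
        y[i] = scratch[i]


@njit(cache=True)
def gene_circuit_rollout(W, B, a, y0, n_steps):
    """Plain rollout; ``a = dt / tau`` per node.  Returns (n_steps+1, n)."""
    n = y0.shape[0]
    out = np.empty((n_steps + 1, n))
    y = y0.copy()
    scratch = np.empty(n)
    out[0] = y
    for t in range(n_steps):
        _step_inplace(W, B, a, y, scratch)
        out[t + 1] = y
    return out


@njit(cache=True)
def _segments_cross(p0x, p0y, p1x, p1y, ax, ay, bx, by):
    """Parametric intersection of P0->P1 with A->B.

    Returns (crosses, t) with t the parameter along P0->P1.
    """
    rx = p1x - p0x
    ry = p1y - p0y
    sx = bx - ax
    sy = by - ay
    denom = rx * sy - ry * sx
    if denom == 0.0:
        return False, 0.0
    qpx = ax - p0x
    qpy = ay - p0y
    t = (qpx * sy - qpy * sx) / denom
    u = (qpx * ry - qpy * rx) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return True, t
    return False, 0.0


@njit(cache=True)
def _resolve_walls(p0x, p0y, p1x, p1y, walls, eps):
    """Project the step P0->P1 so it never ends past a wall segment.

    Sliding along the wall tangent is allowed.  ``walls`` is (nw, 4) rows
    (ax, ay, bx, by).  Returns the corrected endpoint.
    """
    for _ in range(4):
        hit = -1
        t_hit = 2.0
        for w in range(walls.shape[0]):
            crosses, t = _segments_cross(
                p0x, p0y, p1x, p1y, walls[w, 0], walls[w, 1], walls[w, 2], walls[w, 3]
            )
            if crosses and t < t_hit:
                t_hit = t
                hit = w
        if hit < 0:
            return p1x, p1y
        ax, ay = walls[hit, 0], walls[hit, 1]
        bx, by = walls[hit, 2], walls[hit, 3]
        tx = bx - ax
        ty = by - ay
        tn = np.sqrt(tx * tx + ty * ty)
        if tn == 0.0:
            return p0x, p0y
        tx /= tn
        ty /= tn
        # intersection point, pulled back a hair toward P0
        ix = p0x + t_hit * (p1x - p0x)
        iy = p0y + t_hit * (p1y - p0y)
        # remaining displacement past the wall, keep tangential part only
        dx = p1x - ix
        dy = p1y - iy
        dot = dx * tx + dy * ty
        backx = p0x - ix
        backy = p0y - iy
        bn = np.sqrt(backx * backx + backy * backy)
        if bn > 0.0:
            ix += eps * backx / bn
            iy += eps * backy / bn
        p1x = ix + dot * tx
        p1y = iy + dot * ty
    # still crossing after the pass budget: block the step entirely
    for w in range(walls.shape[0]):
        crosses, _t = _segments_cross(
            p0x, p0y, p1x, p1y, walls[w, 0], walls[w, 1], walls[w, 2], walls[w, 3]
        )
        if crosses:
            return p0x, p0y
    return p1x, p1y


@njit(cache=True)
def gene_circuit_rollout_perturbed(
    W,
    B,
    a,
    y0,
    n_steps,
    ev_steps,
    ev_vecs,
    walls,
    wall_i,
    wall_j,
    wall_eps,
    clamp_node,
    clamp_vals,
):
    """Rollout with scheduled displacements, walls and a clamp.

    ev_steps : int64 (ne,) sorted step indices (displacement applied after
               that step's update); ev_vecs (ne, n) displacement vectors.
    walls    : (nw, 4) segments in the (wall_i, wall_j) plane; pass shape
               (0, 4) for none.
    clamp_node/clamp_vals : overwrite node value after each step; clamp_vals
               (n_steps+1,) with NaN meaning "no clamp at this step";
               clamp_node < 0 disables.
    """
    n = y0.shape[0]
    out = np.empty((n_steps + 1, n))
    y = y0.copy()
    if clamp_node >= 0 and not np.isnan(clamp_vals[0]):
        y[clamp_node] = clamp_vals[0]
    out[0] = y
    ev_ptr = 0
    ne = ev_steps.shape[0]
    scratch = np.empty(n)
    for t in range(n_steps):
        prev_i = y[wall_i]
        prev_j = y[wall_j]
        _step_inplace(W, B, a, y, scratch)
        while ev_ptr < ne and ev_steps[ev_ptr] == t + 1:
            for i in range(n):
                y[i] += ev_vecs[ev_ptr, i]
            ev_ptr += 1
        if walls.shape[0] > 0:
            px, py = _resolve_walls(prev_i, prev_j, y[wall_i], y[wall_j], walls, wall_eps)
            y[wall_i] = px
            y[wall_j] = py
        if clamp_node >= 0 and not np.isnan(clamp_vals[t + 1]):
            y[clamp_node] = clamp_vals[t + 1]
        out[t + 1] = y
    return out


@njit(cache=True)
def gene_circuit_loss_grad(W, B, a, y0, n_steps, target, node):
    """Loss sum_t (y[t,node] - target[t])^2 and its exact gradients.

    Reverse-mode differentiation through the unrolled update; returns
    (loss, dy0, dW, dB).  ``target`` has length n_steps + 1.
    """
    n = y0.shape[0]
    ys = np.empty((n_steps + 1, n))
    ss = np.empty((n_steps, n))
    y = y0.copy()
    ys[0] = y
    for t in range(n_steps):
        for i in range(n):
            u = B[i]
            for j in range(n):
                u += W[i, j] * y[j]
            if u >= 0.0:
                s = 1.0 / (1.0 + np.exp(-u))
            else:
                e = np.exp(u)
                s = e / (1.0 + e)
            ss[t, i] = s
        for i in range(n):
            y[i] = a[i] * ss[t, i] + (1.0 - a[i]) * y[i]
        ys[t + 1] = y
    loss = 0.0
    for t in range(n_steps + 1):
        d = ys[t, node] - target[t]
        loss += d * d
    g = np.zeros(n)
    gW = np.zeros((n, n))
    gB = np.zeros(n)
    w = np.empty(n)
    gnew = np.empty(n)
    for t in range(n_steps - 1, -1, -1):
        g[node] += 2.0 * (ys[t + 1, node] - target[t + 1])
        for i in range(n):
            w[i] = a[i] * ss[t, i] * (1.0 - ss[t, i]) * g[i]
        for i in range(n):
            for j in range(n):
                gW[i, j] += w[i] * ys[t, j]
            gB[i] += w[i]
        for j in range(n):
            acc = (1.0 - a[j]) * g[j]
            for i in range(n):
                acc += W[i, j] * w[i]
            gnew[j] = acc
        for j in range(n):
            g[j] = gnew[j]
    g[node] += 2.0 * (ys[0, node] - target[0])
    return loss, g, gW, gB
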
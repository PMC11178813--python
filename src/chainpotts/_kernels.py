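"""Compiled inner loops of the Monte Carlo engine.

Everything here operates on plain arrays so numba can compile it:
``labels`` is the Potts field (0 = ECM, 1..N = cells, N+1 = obstacle),
``vols`` the per-label site counts, ``cx/cyw`` the cell centers (``cyw``
wrapped into [0, L_y)), ``px/py`` the unit polarities, and ``resting``
flags cells whose copies are rejected outright.  Index 0 of the per-cell
arrays is unused padding so cell labels index directly.

The y-direction is periodic; x is clipped (the clipped columns are obstacle
walls in every scenario, so no dynamics are lost at the edge).

:func:`sweep` is the hot loop; it repeats the proposal/rejection sequence
of :func:`try_copy` inline (numba's call overhead per attempt is larger
than the attempt itself), so the two must stay in lockstep.  Both share
:func:`delta_H` for the energy change.

Rejection codes: 0 accepted, 1 same label, 2 illegal (obstacle / out of
lattice / volume-annihilating), 3 resting phase, 4 Metropolis-rejected.
"""

import numpy as np
from numba import njit

# nearest + next-nearest neighborhood (8 sites)
OFF_X = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
OFF_Y = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)

# the same 8 neighbors in cyclic (angular) order, for the connectivity test
CYC_X = np.array([-1, -1, -1, 0, 1, 1, 1, 0], dtype=np.int64)
CYC_Y = np.array([-1, 0, 1, 1, 1, 0, -1, -1], dtype=np.int64)

ACCEPTED, REJ_SAME, REJ_ILLEGAL, REJ_RESTING, REJ_METROPOLIS = 0, 1, 2, 3, 4


@njit(cache=True, fastmath=True, inline="always")
def xi_site(x, y, cx, cyw, px, py, Ly):
    """Direction cosine of site (x, y) seen from center (cx, cyw) along (px, py).

    ``cyw`` must already be wrapped into [0, Ly); the y displacement takes
    the minimal image.  Returns 0.0 when the site coincides with the center
    (unit vector undefined).
    """
    dx = x - cx
    dy = y - cyw
    if dy > 0.5 * Ly:
        dy -= Ly
    elif dy < -0.5 * Ly:
        dy += Ly
    r = np.sqrt(dx * dx + dy * dy)
    if r < 1e-12:
        return 0.0
    return (dx * px + dy * py) / r


@njit(cache=True, fastmath=True, inline="always")
def _static_pair(m, n, gE, gC, gW, obst):
    """Surface-tension + wall energy of one unordered neighboring pair."""
    if m == n:
        return 0.0
    m_cell = (m != 0) and (m != obst)
    n_cell = (n != 0) and (n != obst)
    if m_cell and n_cell:
        return gC
    if m_cell or n_cell:  # one cell, the other ECM or obstacle
        if m == obst or n == obst:
            return gW
        return gE
    return 0.0


@njit(cache=True, fastmath=True)
def delta_H(labels, vols, cx, cyw, px, py, tx, ty, new_label,
            gE, gC, gP, gW, GR, lam, k0, V0, k2, obst):
    """Energy change of relabeling site (tx, ty) to ``new_label``.

    Centers (``cyw``: y wrapped into [0, Ly)) and polarities are held fixed
    (they are slow variables updated once per Monte Carlo step); volumes
    change by +-1 for the two cells involved.  Exact agreement with a full
    recomputation is a tested invariant.
    """
    Lx, Ly = labels.shape
    old = labels[tx, ty]
    new_cell = (new_label != 0) and (new_label != obst)
    old_cell = (old != 0) and (old != obst)
    xi_new = xi_site(tx, ty, cx[new_label], cyw[new_label],
                     px[new_label], py[new_label], Ly) if new_cell else 0.0
    xi_old = xi_site(tx, ty, cx[old], cyw[old],
                     px[old], py[old], Ly) if old_cell else 0.0

    dH = 0.0
    for k in range(8):
        nx = tx + OFF_X[k]
        if nx < 0 or nx >= Lx:
            continue
        ny = (ty + OFF_Y[k]) % Ly
        c = labels[nx, ny]
        dH += _static_pair(new_label, c, gE, gC, gW, obst)
        dH -= _static_pair(old, c, gE, gC, gW, obst)
        if c != 0 and c != obst:
            # motility + adhesion act on cell-cell pairs with distinct labels
            if old_cell and c != old:
                xic = xi_site(nx, ny, cx[c], cyw[c], px[c], py[c], Ly)
                dH -= -gP * (xi_old + xic) \
                    - GR * (1.0 + lam * xi_old) * (1.0 + lam * xic)
            if new_cell and c != new_label:
                xic = xi_site(nx, ny, cx[c], cyw[c], px[c], py[c], Ly)
                dH += -gP * (xi_new + xic) \
                    - GR * (1.0 + lam * xi_new) * (1.0 + lam * xic)

    if new_cell:
        v = vols[new_label]
        dH += k0 * V0 * ((1.0 - (v + 1.0) / V0) ** 2 - (1.0 - v / V0) ** 2)
        dH += k2 * (1.0 - xi_new * xi_new)
    if old_cell:
        v = vols[old]
        dH += k0 * V0 * ((1.0 - (v - 1.0) / V0) ** 2 - (1.0 - v / V0) ** 2)
        dH -= k2 * (1.0 - xi_old * xi_old)
    return dH


@njit(cache=True, inline="always")
def _locally_disconnects(labels, tx, ty, b):
    """True if relabeling (tx, ty) away from cell ``b`` would split ``b`` locally.

    Walks the 8 neighbors in cyclic order and counts the arcs of
    ``b``-labeled sites around the target; more than one arc means the
    target bridges separate parts of the cell, so removing it would
    (locally) disconnect the cell.  Out-of-lattice x counts as not-``b``.
    """
    Lx, Ly = labels.shape
    arcs = 0
    nx = tx + CYC_X[7]
    ny = (ty + CYC_Y[7]) % Ly
    prev = (0 <= nx < Lx) and labels[nx, ny] == b
    for k in range(8):
        nx = tx + CYC_X[k]
        ny = (ty + CYC_Y[k]) % Ly
        cur = (0 <= nx < Lx) and labels[nx, ny] == b
        if cur and not prev:
            arcs += 1
        prev = cur
    return arcs > 1


@njit(cache=True)
def try_copy(labels, vols, cx, cyw, px, py, resting,
             sx, sy, k,
             gE, gC, gP, gW, GR, lam, k0, V0, k2, beta, obst, conn):
    """One copy attempt from source (sx, sy) to its k-th neighbor.

    The uniform variate for the Metropolis decision is drawn from the
    compiled RNG stream only when an energy-raising proposal reaches the
    acceptance test.  Mutates ``labels`` and ``vols`` on acceptance and
    returns a rejection code.
    """
    Lx, Ly = labels.shape
    tx = sx + OFF_X[k]
    if tx < 0 or tx >= Lx:
        return REJ_ILLEGAL
    ty = (sy + OFF_Y[k]) % Ly
    src = labels[sx, sy]
    tgt = labels[tx, ty]
    if src == tgt:
        return REJ_SAME
    if src == obst or tgt == obst:
        return REJ_ILLEGAL
    if tgt != 0 and vols[tgt] <= 1:
        return REJ_ILLEGAL  # would annihilate a cell; N is conserved
    if conn and tgt != 0 and _locally_disconnects(labels, tx, ty, tgt):
        return REJ_ILLEGAL  # cells stay connected
    if (src != 0 and resting[src]) or (tgt != 0 and resting[tgt]):
        return REJ_RESTING
    dH = delta_H(labels, vols, cx, cyw, px, py, tx, ty, src,
                 gE, gC, gP, gW, GR, lam, k0, V0, k2, obst)
    if dH > 0.0 and np.random.random() >= np.exp(-beta * dH):
        return REJ_METROPOLIS
    labels[tx, ty] = src
    if src != 0:
        vols[src] += 1
    if tgt != 0:
        vols[tgt] -= 1
    return ACCEPTED


@njit(cache=True, fastmath=True)
def sweep(labels, vols, cx, cyw, px, py, resting, n_attempts,
          gE, gC, gP, gW, GR, lam, k0, V0, k2, beta, obst, conn, counts):
    """Run ``n_attempts`` random copy attempts; tally outcomes in ``counts``.

    Source site and neighbor direction are decoded from a single uniform
    draw (8 L_x L_y equiprobable proposals, far below the 53-bit resolution
    of the generator).  The body repeats :func:`try_copy` inline.
    """
    Lx, Ly = labels.shape
    n_prop = Lx * Ly * 8
    for _ in range(n_attempts):
        idx = int(np.random.random() * n_prop)
        k = idx & 7
        site = idx >> 3
        sx = site // Ly
        sy = site - sx * Ly
        tx = sx + OFF_X[k]
        if tx < 0 or tx >= Lx:
            counts[REJ_ILLEGAL] += 1
            continue
        ty = (sy + OFF_Y[k]) % Ly
        src = labels[sx, sy]
        tgt = labels[tx, ty]
        if src == tgt:
            counts[REJ_SAME] += 1
            continue
        if src == obst or tgt == obst:
            counts[REJ_ILLEGAL] += 1
            continue
        if tgt != 0 and vols[tgt] <= 1:
            counts[REJ_ILLEGAL] += 1
            continue
        if conn and tgt != 0 and _locally_disconnects(labels, tx, ty, tgt):
            counts[REJ_ILLEGAL] += 1
            continue
        if (src != 0 and resting[src]) or (tgt != 0 and resting[tgt]):
            counts[REJ_RESTING] += 1
            continue
        dH = delta_H(labels, vols, cx, cyw, px, py, tx, ty, src,
                     gE, gC, gP, gW, GR, lam, k0, V0, k2, obst)
        if dH > 0.0 and np.random.random() >= np.exp(-beta * dH):
            counts[REJ_METROPOLIS] += 1
            continue
        labels[tx, ty] = src
        if src != 0:
            vols[src] += 1
        if tgt != 0:
            vols[tgt] -= 1
        counts[ACCEPTED] += 1


@njit(cache=True)
def centroids(labels, n_cells, ref_cy, out_x, out_y, out_v):
    """Per-cell centroids, y unwrapped relative to the reference centers.

    Each site's y enters as the minimal-image offset from ``ref_cy`` (the
    cell's center at the previous step), which is exact while cells span
    less than half the channel length.
    """
    Lx, Ly = labels.shape
    out_x[:] = 0.0
    out_y[:] = 0.0
    out_v[:] = 0
    for x in range(Lx):
        for y in range(Ly):
            m = labels[x, y]
            if 1 <= m <= n_cells:
                dy = y - (ref_cy[m] % Ly)
                dy -= Ly * np.round(dy / Ly)
                out_x[m] += x
                out_y[m] += ref_cy[m] + dy
                out_v[m] += 1
    for m in range(1, n_cells + 1):
        if out_v[m] > 0:
            out_x[m] /= out_v[m]
            out_y[m] /= out_v[m]


@njit(cache=True, inline="always")
def rotate_polarity(px, py, dx, dy, inv_a_tau):
    """Leap-frog polarity update: rotate (px, py) toward displacement (dx, dy).

    dp = (d - (p.d) p) / (a tau) is orthogonal to p; p is rotated in-plane
    by |dp| toward the side given by the sign of the cross product, which
    keeps |p| = 1 exactly.
    """
    pd = px * dx + py * dy
    qx = (dx - pd * px) * inv_a_tau
    qy = (dy - pd * py) * inv_a_tau
    ang = np.sqrt(qx * qx + qy * qy)
    if ang == 0.0:
        return px, py
    if px * qy - py * qx < 0.0:
        ang = -ang
    c = np.cos(ang)
    s = np.sin(ang)
    return c * px - s * py, s * px + c * py


@njit(cache=True)
def post_sweep_update(labels, n_cells, cx, cy, px, py, inv_a_tau,
                      new_x, new_y, new_v):
    """Center + polarity update after a Monte Carlo step.

    Recomputes centroids, rotates each polarity toward its half-step
    displacement, then commits the new centers in place.
    """
    centroids(labels, n_cells, cy, new_x, new_y, new_v)
    for m in range(1, n_cells + 1):
        dx = new_x[m] - cx[m]
        dy = new_y[m] - cy[m]
        px[m], py[m] = rotate_polarity(px[m], py[m], dx, dy, inv_a_tau)
        cx[m] = new_x[m]
        cy[m] = new_y[m]


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (independent of numpy's Python-side state)."""
    np.random.seed(seed)


@njit(cache=True)
def contact_pairs(labels, obst):
    """Count unordered neighboring site pairs with two distinct cell labels."""
    Lx, Ly = labels.shape
    n = 0
    for x in range(Lx):
        for y in range(Ly):
            m = labels[x, y]
            for k in range(8):
                if OFF_X[k] < 0 or (OFF_X[k] == 0 and OFF_Y[k] < 0):
                    continue  # forward pairs only: count each pair once
                nx = x + OFF_X[k]
                if nx >= Lx:
                    continue
                ny = (y + OFF_Y[k]) % Ly
                c = labels[nx, ny]
                if m != c and m != 0 and c != 0 and m != obst and c != obst:
                    n += 1
    return n
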
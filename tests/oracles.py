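"""Independent brute-force energy oracle for the test suite.

Deliberately written from scratch against the printed term definitions,
with a different pair-enumeration strategy than the package (ordered pairs
double-counted then halved, symmetric indicator brackets evaluated
literally) and its own direction-cosine arithmetic, so agreement with the
package is a genuine cross-check rather than a tautology.
"""

import math

import numpy as np


def _neighbors(x, y, Lx, Ly):
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == dy == 0:
                continue
            nx = x + dx
            if 0 <= nx < Lx:
                yield nx, (y + dy) % Ly


def _xi(x, y, center, polarity, Ly):
    dx = x - center[0]
    dy = math.remainder(y - center[1], Ly)
    r = math.hypot(dx, dy)
    if r < 1e-12:
        return 0.0
    return (dx * polarity[0] + dy * polarity[1]) / r


def oracle_energy(labels, cells, params, n_cells=None):
    """All five Hamiltonian terms by literal double-loop evaluation.

    ``cells`` maps label -> (center, polarity).  Returns a dict with keys
    H_st, H_v, H_m, H_cca, H_w, H_total.
    """
    labels = np.asarray(labels)
    Lx, Ly = labels.shape
    n = n_cells if n_cells is not None else max(cells) if cells else 0
    obst = n + 1

    def theta(m):
        return 0 if m in (0, obst) else 1

    H_st = H_m = H_cca = H_w = 0.0
    for x in range(Lx):
        for y in range(Ly):
            m = int(labels[x, y])
            for nx, ny in _neighbors(x, y, Lx, Ly):
                mn = int(labels[nx, ny])
                eta = 0 if m == mn else 1
                if not eta:
                    continue
                # each ordered pair visited twice -> add half
                H_st += 0.5 * params.gamma_E * (
                    theta(m) * (mn == 0) + theta(mn) * (m == 0)
                )
                H_st += 0.5 * params.gamma_C * theta(m) * theta(mn)
                H_w += 0.5 * params.gamma_W * (
                    theta(m) * (mn == obst) + theta(mn) * (m == obst)
                )
                if theta(m) and theta(mn):
                    xi_m = _xi(x, y, *cells[m], Ly)
                    xi_n = _xi(nx, ny, *cells[mn], Ly)
                    H_m += 0.5 * (-params.gamma_P) * (xi_m + xi_n)
                    H_cca += 0.5 * (-params.Gamma_R) \
                        * (1 + params.lam * xi_m) * (1 + params.lam * xi_n)

    H_v = 0.0
    for m, (center, polarity) in cells.items():
        vol = int((labels == m).sum())
        H_v += params.kappa_0 * params.V_0 * (1 - vol / params.V_0) ** 2
        for x, y in zip(*np.nonzero(labels == m)):
            xi = _xi(x, y, center, polarity, Ly)
            H_v += params.kappa_2 * (1 - xi * xi)

    total = H_st + H_v + H_m + H_cca + H_w
    return dict(H_st=H_st, H_v=H_v, H_m=H_m, H_cca=H_cca, H_w=H_w,
                H_total=total)


def oracle_delta(labels, cells, params, source, target, n_cells=None):
    """Full-recomputation energy difference for one copy, centers frozen."""
    before = oracle_energy(labels, cells, params, n_cells)["H_total"]
    after_labels = np.array(labels, copy=True)
    after_labels[target] = labels[source]
    after = oracle_energy(after_labels, cells, params, n_cells)["H_total"]
    return after - before
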
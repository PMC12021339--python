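"""Independent brute-force oracles used only by the tests.

Each function recomputes a quantity with plain loops / exhaustive
enumeration, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ssim_global(x, y, c1, c2, c3):
    """Three-factor SSIM from whole-volume statistics, loop implementation."""
    xs = [float(v) for v in np.ravel(x)]
    ys = [float(v) for v in np.ravel(y)]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    vx = sum((v - mx) ** 2 for v in xs) / (n - 1)
    vy = sum((v - my) ** 2 for v in ys) / (n - 1)
    cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / (n - 1)
    sx, sy = math.sqrt(vx), math.sqrt(vy)
    return (
        (2 * mx * my + c1)
        / (mx**2 + my**2 + c1)
        * (2 * sx * sy + c2)
        / (vx + vy + c2)
        * (cov + c3)
        / (sx * sy + c3)
    )


def snr(values):
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return mean / sd


def cnr(values_a, values_b):
    va = [float(v) for v in values_a]
    vb = [float(v) for v in values_b]
    ma = sum(va) / len(va)
    mb = sum(vb) / len(vb)
    sa2 = sum((v - ma) ** 2 for v in va) / (len(va) - 1)
    sb2 = sum((v - mb) ** 2 for v in vb) / (len(vb) - 1)
    return abs(ma - mb) / math.sqrt(sa2 + sb2)


def dice(g, p):
    g = np.asarray(g, bool)
    p = np.asarray(p, bool)
    inter = int(np.logical_and(g, p).sum())
    return 2.0 * inter / (int(g.sum()) + int(p.sum()))


def _boundary_points(mask, spacing):
    """Foreground voxels with a face-adjacent background neighbor (out of
    bounds counts as background), as physical coordinates."""
    mask = np.asarray(mask, bool)
    pts = []
    for idx in np.argwhere(mask):
        i, j, k = (int(v) for v in idx)
        on_surface = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1] and 0 <= nk < mask.shape[2]):
                on_surface = True
                break
            if not mask[ni, nj, nk]:
                on_surface = True
                break
        if on_surface:
            pts.append((i * spacing[0], j * spacing[1], k * spacing[2]))
    return pts


def assd(g, p, spacing=(1.0, 1.0, 1.0)):
    """All-pairs O(Ng*Np) average symmetric surface distance in mm."""
    bg = _boundary_points(g, spacing)
    bp = _boundary_points(p, spacing)
    total = 0.0
    for a in bg:
        total += min(math.dist(a, b) for b in bp)
    for b in bp:
        total += min(math.dist(a, b) for a in bg)
    return total / (len(bg) + len(bp))


def wilcoxon_exact_p(differences):
    """Two-sided exact signed-rank p-value by full 2^n sign enumeration.

    Requires nonzero, tie-free |differences|.
    """
    d = [float(v) for v in differences if v != 0]
    n = len(d)
    ranks = {}
    for r, v in enumerate(sorted(abs(x) for x in d), start=1):
        ranks[v] = r
    w_obs = sum(ranks[abs(v)] for v in d if v > 0)
    w_mean = n * (n + 1) / 4.0
    dev_obs = abs(w_obs - w_mean)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(ranks[abs(v)] for v, s in zip(d, signs) if s)
        if abs(w - w_mean) >= dev_obs - 1e-12:
            count += 1
    return count / 2.0**n


def otsu_exhaustive(values):
    """Threshold maximizing between-class variance over all midpoints of
    consecutive distinct values."""
    vals = np.sort(np.asarray(values, float))
    distinct = np.unique(vals)
    best_t, best_var = distinct[0], -1.0
    n = vals.size
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = 0.5 * (lo + hi)
        below = vals[vals <= t]
        above = vals[vals > t]
        w0, w1 = below.size / n, above.size / n
        var = w0 * w1 * (below.mean() - above.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def mprage_like_ratio(t1w, pdw, mtw, variant, lam):
    """Loop evaluation of the regularized ratio, no clipping."""
    t1w = np.asarray(t1w, float)
    out = np.zeros_like(t1w)
    it = np.nditer(t1w, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        if variant == "all":
            den = 0.5 * (pdw[idx] + mtw[idx])
        elif variant == "MT":
            den = mtw[idx]
        else:
            den = pdw[idx]
        if den + lam != 0:
            out[idx] = (t1w[idx] - lam) / (den + lam)
    return out
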
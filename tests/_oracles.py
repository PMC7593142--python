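"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops directly from the
probabilistic definitions, deliberately sharing no code with the vectorized
implementation it checks.
"""

from __future__ import annotations

import math


def _p_detect(form, g0, sigma, d):
    if form == "hazard-exponential":
        lam0 = -math.log(1.0 - g0)
        return 1.0 - math.exp(-lam0 * math.exp(-d / sigma))
    return g0 * math.exp(-d * d / (2.0 * sigma * sigma))


def _level(structure, s, post):
    if structure == "constant":
        return 0
    if structure == "time":
        return s
    return post


def brute_force_nll(omega, det_xy, mask_xy, cell_area_km2, usage,
                    g0_levels, sigma_levels, form="hazard-exponential",
                    g0_structure="constant", sigma_structure="constant"):
    """Conditional negative log-likelihood by direct summation.

    omega: nested list [i][s][k] of 0/1; usage: [k][s] of 0/1.
    """
    n = len(omega)
    S = len(omega[0])
    K = len(det_xy)
    M = len(mask_xy)

    def prob(i, s, k, x, post):
        g0 = g0_levels[_level(g0_structure, s, post)]
        sg = sigma_levels[_level(sigma_structure, s, post)]
        d = math.dist(det_xy[k], mask_xy[x])
        return _p_detect(form, g0, sg, d)

    # effective sampling area at the naive level
    a = 0.0
    for x in range(M):
        surv = 1.0
        for s in range(S):
            for k in range(K):
                if usage[k][s]:
                    surv *= 1.0 - prob(0, s, k, x, post=0)
        a += (1.0 - surv) * cell_area_km2
    if a <= 0:
        return float("inf")

    total = 0.0
    for i in range(n):
        integral = 0.0
        for x in range(M):
            pr = 1.0
            seen = False  # prior capture state, occasion by occasion
            for s in range(S):
                post = 1 if seen else 0
                for k in range(K):
                    if not usage[k][s]:
                        continue
                    p = prob(i, s, k, x, post)
                    pr *= p if omega[i][s][k] else (1.0 - p)
                if any(omega[i][s][k] for k in range(K)):
                    seen = True
            integral += pr * cell_area_km2
        total += math.log(integral / a)
    return -total


def brute_force_pdot(det_xy, loc, usage, g0, sigma, n_occasions,
                     form="hazard-exponential"):
    """1 - prod over used detector-occasions of (1 - p), by enumeration."""
    surv = 1.0
    for s in range(n_occasions):
        for k, xy in enumerate(det_xy):
            if usage[k][s]:
                surv *= 1.0 - _p_detect(form, g0, sigma, math.dist(xy, loc))
    return 1.0 - surv


def pearson_r(xs, ys):
    """Plain covariance / (sd * sd) evaluation."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)
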
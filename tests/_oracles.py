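"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: dominance is decided
straight from its definition (pairwise comparison; beaten by a convex blend
of two other strategies), enumerating all candidate pairs.
"""

from __future__ import annotations

from adtcea.cea_stats import EXTENDED_DOMINATED, ON_FRONTIER, STRICTLY_DOMINATED


def _blend_dominates(cj, qj, ck, qk, ci, qi) -> bool:
    """Is some convex blend of points j and k at least as cheap and at least
    as effective as point i, with one inequality strict?"""
    # feasible lambda interval for cost(lambda) <= ci, lambda = weight on j
    lo, hi = 0.0, 1.0

    def clip(a, b, bound, sense):
        # a + lam * b  (sense '<=' bound or '>=' bound) -> lambda interval
        nonlocal lo, hi
        if b == 0:
            if (sense == "le" and a > bound) or (sense == "ge" and a < bound):
                return False
            return True
        x = (bound - a) / b
        if (b > 0) == (sense == "le"):
            hi = min(hi, x)
        else:
            lo = max(lo, x)
        return True

    # cost: ck + lam*(cj-ck) <= ci ; qaly: qk + lam*(qj-qk) >= qi
    if not clip(ck, cj - ck, ci, "le"):
        return False
    if not clip(qk, qj - qk, qi, "ge"):
        return False
    if lo > hi:
        return False
    # some feasible blend exists; require a strict improvement somewhere
    for lam in (lo, hi, 0.5 * (lo + hi)):
        c = ck + lam * (cj - ck)
        q = qk + lam * (qj - qk)
        if c <= ci and q >= qi and (c < ci or q > qi):
            return True
    return False


def frontier_oracle(points: list[tuple[float, float]]) -> list[str]:
    """Dominance status per (cost, qaly) point by exhaustive enumeration.

    Strictly dominated: some other point is at least as cheap and at least
    as effective, with one strict (exact duplicates keep the first by input
    order).  Extended dominated: not strictly dominated, but beaten by a
    convex blend of two non-strictly-dominated points.
    """
    n = len(points)
    status = [ON_FRONTIER] * n
    for i, (ci, qi) in enumerate(points):
        for j, (cj, qj) in enumerate(points):
            if i == j:
                continue
            if cj == ci and qj == qi:
                if j < i:
                    status[i] = STRICTLY_DOMINATED
                continue
            if cj <= ci and qj >= qi:
                status[i] = STRICTLY_DOMINATED
    candidates = [i for i in range(n) if status[i] == ON_FRONTIER]
    for i in candidates:
        ci, qi = points[i]
        beaten = False
        for j in candidates:
            if beaten or j == i:
                continue
            for k in candidates:
                if k == i or k == j:
                    continue
                cj, qj = points[j]
                ck, qk = points[k]
                if _blend_dominates(cj, qj, ck, qk, ci, qi):
                    beaten = True
                    break
        if beaten:
            status[i] = EXTENDED_DOMINATED
    return status
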
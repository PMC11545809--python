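"""Brute-force oracles shared by the unit and end-to-end test suites."""

import itertools

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Connected components by BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                queue, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while queue:
                    r, c = queue.pop()
                    comp.append((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                comps.append(frozenset(comp))
    return set(comps)


def brute_force_u(case, control):
    """U as the count of (case > control) pairs plus half-ties."""
    u = 0.0
    for x in case:
        for y in control:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def brute_force_mwu_exact_p(case, control, alternative="two-sided"):
    """Exact MWU p by enumerating every labeling of the pooled sample."""
    pooled = list(case) + list(control)
    n1, n2 = len(case), len(control)
    u_obs = brute_force_u(case, control)
    mid = n1 * n2 / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = brute_force_u(grp, rest)
        total += 1
        if alternative == "greater":
            count += u >= u_obs
        elif alternative == "less":
            count += u <= u_obs
        else:
            count += abs(u - mid) >= abs(u_obs - mid) - 1e-12
    return count / total
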
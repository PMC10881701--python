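"""Brute-force reference implementations used only to check the package.

Deliberately written in plain loops with none of the library's vectorized
machinery, so they constitute an independent route to the same answers.
"""

from fractions import Fraction
from itertools import product
from math import factorial, sqrt

import numpy as np


def brute_segment(values, rough_indices, threshold_fraction=0.42):
    """Threshold-then-flood-fill segmentation oracle.

    Keeps rough-VOI voxels >= threshold_fraction * max(rough values), then
    returns the 26-connected component containing the (lexicographically
    first) maximum voxel.
    """
    rough = sorted(tuple(i) for i in rough_indices)
    vals = {idx: values[idx] for idx in rough}
    vmax = max(vals.values())
    max_voxel = min(idx for idx, v in vals.items() if v == vmax)
    passed = {idx for idx, v in vals.items() if v >= threshold_fraction * vmax}
    component = set()
    stack = [max_voxel]
    while stack:
        cur = stack.pop()
        if cur in component or cur not in passed:
            continue
        component.add(cur)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    stack.append((cur[0] + di, cur[1] + dj, cur[2] + dk))
    return component


def brute_peak(values, voi_indices, spacing, radius=5.0):
    """Peak-uptake oracle: scan every grid voxel for sphere membership."""
    voi = sorted(tuple(i) for i in voi_indices)
    vmax = max(values[idx] for idx in voi)
    center_idx = min(idx for idx in voi if values[idx] == vmax)
    center = tuple(center_idx[a] * spacing[a] for a in range(3))
    members = []
    for idx in product(*(range(n) for n in values.shape)):
        d = sqrt(sum((idx[a] * spacing[a] - center[a]) ** 2 for a in range(3)))
        if d <= radius:
            members.append(values[idx])
    return sum(members) / len(members)


def brute_fisher_2or3_rows(table):
    """Exact Fisher p for a 2- or 3-row table by exhaustive composition.

    Enumerates every non-negative matrix with the observed margins using
    itertools products of the free rows (last row forced), with exact
    rational arithmetic for the conditional probabilities.
    """
    obs = [list(map(int, row)) for row in table]
    rows = [sum(r) for r in obs]
    cols = [sum(obs[i][j] for i in range(len(obs))) for j in range(len(obs[0]))]
    n = sum(rows)

    def prob(t):
        num = Fraction(1)
        for r in rows:
            num *= factorial(r)
        for c in cols:
            num *= factorial(c)
        den = Fraction(factorial(n))
        for row in t:
            for x in row:
                den *= factorial(x)
        return num / den

    def compositions(total, ncells, caps):
        if ncells == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for x in range(min(total, caps[0]) + 1):
            for rest in compositions(total - x, ncells - 1, caps[1:]):
                yield (x,) + rest

    p_obs = prob(obs)
    p_sum = Fraction(0)
    free = obs[:-1]
    for filled in product(*(compositions(sum(r), len(cols), cols) for r in free)):
        last = [cols[j] - sum(f[j] for f in filled) for j in range(len(cols))]
        if any(x < 0 for x in last) or sum(last) != rows[-1]:
            continue
        t = [list(f) for f in filled] + [last]
        p = prob(t)
        if p <= p_obs:
            p_sum += p
    return float(p_sum)
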
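"""Independent brute-force oracles used to audit the analysis primitives.

Deliberately naive implementations — exhaustive enumeration, per-bp
marking, pairwise graph clustering — kept free of any code shared with the
package so the comparisons are meaningful.
"""

from __future__ import annotations

import math

import numpy as np

from introskim.deviation import DeviationProfile
from introskim.genome import Chromosome, GenomeSpec, make_windows


def single_chrom_profile(values, subgenome="A", window=1_000_000):
    """A profile over one chromosome whose windows carry ``values``.

    Returns (profile, spec); NaN entries count as masked windows.
    """
    values = np.asarray(values, dtype=float)
    spec = GenomeSpec(
        [Chromosome(name=f"1{subgenome}", length=len(values) * window,
                    subgenome=subgenome, group=1)]
    )
    grid = make_windows(spec, window)
    prof = DeviationProfile.empty("S", grid)
    prof.values[:] = values
    prof.masked[:] = np.isnan(values)
    return prof, spec


def brute_force_runs(values, pred, min_run: int, bridge_gap: int):
    """Exhaustive maximal-run enumeration over one chromosome's windows.

    A run is a pair of satisfying indices (i, j) such that consecutive
    satisfying indices inside [i, j] are separated by at most
    ``bridge_gap`` interrupting windows, holding >= ``min_run`` satisfying
    windows, and extendable in neither direction. Returns a list of
    (first_index, last_index, n_satisfying).
    """
    values = np.asarray(values, dtype=float)
    sat = [i for i in range(len(values)) if not math.isnan(values[i]) and pred(values[i])]

    def valid(a: int, b: int) -> bool:
        inside = [i for i in sat if sat[a] <= i <= sat[b]]
        return all(y - x - 1 <= bridge_gap for x, y in zip(inside, inside[1:]))

    out = []
    for a in range(len(sat)):
        for b in range(a, len(sat)):
            if not valid(a, b):
                continue
            if a > 0 and valid(a - 1, b):
                continue
            if b < len(sat) - 1 and valid(a, b + 1):
                continue
            n = sum(1 for i in sat if sat[a] <= i <= sat[b])
            if n >= min_run:
                out.append((sat[a], sat[b], n))
    return out


def brute_force_union_coverage(intervals, length: int) -> int:
    """Per-bp marking union coverage on a small chromosome."""
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[max(0, s) : min(length, e)] = True
    return int(covered.sum())


def brute_force_clusters(positions, tolerance: int):
    """Single-linkage via explicit pairwise graph + BFS components.

    Returns a sorted list of frozensets of member indices.
    """
    n = len(positions)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= tolerance:
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        queue, comp = [i], set()
        while queue:
            k = queue.pop()
            if k in comp:
                continue
            comp.add(k)
            queue.extend(adj[k])
        seen |= comp
        comps.append(frozenset(comp))
    return sorted(comps, key=lambda c: min(positions[i] for i in c))


def brute_force_detectable(start: int, end: int, marker_positions) -> bool:
    return any(start <= p < end for p in marker_positions)
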
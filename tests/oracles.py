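"""Independent brute-force oracles used to verify the implementation.

Everything here is written naively (plain Python, exhaustive enumeration)
and stays independent of the package's own code paths.
"""

from __future__ import annotations

import itertools


def sw_oracle(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
              gap: float = -2.0) -> tuple[float, int, int]:
    """Plain-Python Smith-Waterman.

    Returns (score, matches, span) of the best local alignment, using the
    same conventions as the implementation: best end cell = first maximum in
    row-major order, traceback preference diagonal > up > left.
    """
    a, b = a.upper(), b.upper()
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = v
            if v > best:
                best, bi, bj = v, i, j
    i, j = bi, bj
    matches = span = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        elif H[i][j] == H[i][j - 1] + gap:
            j -= 1
        else:
            break
        span += 1
    return best, matches, span


def te_flag_oracle(probe: str, repeats: dict[str, str], min_identity: float = 0.80,
                   min_span: int = 45) -> bool:
    """Flag decision from the naive aligner: best-scoring alignment over all
    repeats, then the identity/span rule."""
    best = (-1.0, 0, 0)
    for seq in repeats.values():
        res = sw_oracle(probe, seq)
        if res[0] > best[0]:
            best = res
    score, matches, span = best
    return span >= min_span and (matches / span if span else 0.0) >= min_identity


def resolve_oracle(coords: dict[str, list], pm) -> tuple[list, str] | None:
    """Exhaustive re-derivation of covering-well-set resolution.

    Enumerates every subset (size 1..3) of the candidate-well product,
    keeps subsets that use all positive coordinates and whose wells all
    hold BACs, and applies the same acceptance rules as the implementation:
    unique mutually-overlapping set at the smallest feasible size, else a
    unique disjoint-contig pair.
    """
    axes = ("plate", "row", "column")
    if any(len(coords[a]) == 0 for a in axes):
        return None
    product = [
        (p, r, c)
        for p in coords["plate"]
        for r in coords["row"]
        for c in coords["column"]
    ]
    req = {a: set(coords[a]) for a in axes}
    for size in (1, 2, 3):
        overlapping, disjoint = [], []
        for combo in itertools.combinations(product, size):
            if {w[0] for w in combo} != req["plate"]:
                continue
            if {w[1] for w in combo} != req["row"]:
                continue
            if {w[2] for w in combo} != req["column"]:
                continue
            bacs = [pm.bac_at(w) for w in combo]
            if None in bacs or len(set(bacs)) != len(bacs):
                continue
            ok = all(
                pm.overlap(x, y) for x, y in itertools.combinations(bacs, 2)
            )
            if size == 1 or ok:
                overlapping.append(combo)
            elif (
                size == 2
                and all(len(req[a]) == 2 for a in axes)
                and pm.contig_of(bacs[0]) != pm.contig_of(bacs[1])
            ):
                disjoint.append(combo)
        if len(overlapping) == 1:
            return list(overlapping[0]), "overlapping"
        if len(overlapping) > 1:
            return None
        if len(disjoint) == 1:
            return list(disjoint[0]), "duplicated"
        if disjoint:
            return None
    return None


def components_oracle(nodes: list[str], edges: list[tuple[str, str]]) -> set[frozenset]:
    """Connected components by repeated breadth-first search."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        queue, comp = [n], set()
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
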
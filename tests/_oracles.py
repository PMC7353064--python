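"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration, BFS, explicit step-up) and
shares no code with the implementation it checks.
"""

from itertools import combinations


def hypergeom_tail_enumerated(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustively enumerating all C(N, n) draws.

    The urn holds N balls of which K are marked; count draws of size n with
    at least k marked balls.
    """
    balls = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(balls, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def bh_stepup(p_values):
    """Benjamini-Hochberg step-up, written out literally.

    Sort ascending, compute p*(m/rank), enforce monotonicity from the
    largest rank down, cap at 1, and restore input order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p_values[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def bfs_ancestors(parents: dict, start):
    """Reflexive transitive closure by breadth-first search over parents."""
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for node in frontier:
            for parent in parents.get(node, ()):
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return seen
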
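"""Independent brute-force oracles used by the test suite."""

import itertools

from fragsig.mapping import FragmentGraph


def brute_force_maximal_mappings(qgraph: FragmentGraph, tgraph: FragmentGraph):
    """All consistent injective mappings not contained in a larger one."""

    def consistent(links):
        for (q1, t1), (q2, t2) in itertools.combinations(links, 2):
            if qgraph.adjacent(q1, q2) and not tgraph.adjacent(t1, t2):
                return False
        return True

    all_consistent = set()
    for k in range(1, min(qgraph.n, tgraph.n) + 1):
        for q_sub in itertools.combinations(range(qgraph.n), k):
            for t_perm in itertools.permutations(range(tgraph.n), k):
                links = frozenset(zip(q_sub, t_perm))
                if consistent(links):
                    all_consistent.add(links)
    return {
        m for m in all_consistent if not any(m < other for other in all_consistent)
    }


def brute_force_contiguous_mappings(m: int, n: int):
    """Single links plus oriented contiguous interval maps between two paths."""
    mappings = {frozenset([(q, t)]) for q in range(m) for t in range(n)}
    for k in range(2, min(m, n) + 1):
        for q0 in range(m - k + 1):
            for t0 in range(n - k + 1):
                mappings.add(frozenset((q0 + i, t0 + i) for i in range(k)))
                mappings.add(frozenset((q0 + i, t0 + k - 1 - i) for i in range(k)))
    return mappings
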
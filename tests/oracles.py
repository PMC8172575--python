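"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a different route than the library:
weighted edit-distance dynamic programming instead of LCS, exhaustive
window/partition enumeration, Floyd-Warshall transitive closure instead of
union-find.
"""

from __future__ import annotations


def weighted_edit_distance(a: str, b: str) -> int:
    """Wagner-Fischer DP with insert/delete cost 1, substitution cost 2."""
    n, m = len(a), len(b)
    dist = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dist[i][0] = i
    for j in range(m + 1):
        dist[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1][j - 1] + (0 if a[i - 1] == b[j - 1] else 2)
            dist[i][j] = min(dist[i - 1][j] + 1, dist[i][j - 1] + 1, sub)
    return dist[n][m]


def oracle_ratio(a: str, b: str) -> float:
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return 1.0 - weighted_edit_distance(a, b) / total


def oracle_partial_ratio(a: str, b: str) -> float:
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    if len(shorter) == len(longer):
        return oracle_ratio(a, b)
    if not shorter:
        return 1.0
    n = len(shorter)
    return max(
        oracle_ratio(shorter, longer[i : i + n]) for i in range(len(longer) - n + 1)
    )


def oracle_token_sort_ratio(a: str, b: str) -> float:
    return oracle_ratio(
        " ".join(sorted(a.lower().split())), " ".join(sorted(b.lower().split()))
    )


def oracle_token_set_ratio(a: str, b: str) -> float:
    ta, tb = set(a.lower().split()), set(b.lower().split())
    inter = sorted(ta & tb)
    t0 = " ".join(inter)
    t1 = " ".join(inter + sorted(ta - tb))
    t2 = " ".join(inter + sorted(tb - ta))
    return max(oracle_ratio(t0, t1), oracle_ratio(t0, t2), oracle_ratio(t1, t2))


def oracle_numeric_similarity(a: str, b: str) -> float:
    """Digit-run multiset Jaccard via a manual scan (no regex)."""

    def runs(s: str) -> list[str]:
        out, current = [], ""
        for c in s:
            if c.isdigit():
                current += c
            elif current:
                out.append(current)
                current = ""
        if current:
            out.append(current)
        return out

    ra, rb = runs(a), runs(b)
    if not ra and not rb:
        return 1.0
    inter = 0
    rb_pool = list(rb)
    for run in ra:
        if run in rb_pool:
            rb_pool.remove(run)
            inter += 1
    union = len(ra) + len(rb) - inter
    return inter / union


ORACLES = {
    "ratio": oracle_ratio,
    "partial_ratio": oracle_partial_ratio,
    "token_sort_ratio": oracle_token_sort_ratio,
    "token_set_ratio": oracle_token_set_ratio,
    "numeric_similarity": oracle_numeric_similarity,
}


def closure_partition(n_nodes: int, edges: list[tuple[int, int]]) -> list[frozenset[int]]:
    """Partition of 0..n-1 by Floyd-Warshall transitive closure of the edges."""
    reach = [[i == j for j in range(n_nodes)] for i in range(n_nodes)]
    for a, b in edges:
        reach[a][b] = reach[b][a] = True
    for k in range(n_nodes):
        for i in range(n_nodes):
            if reach[i][k]:
                row_i, row_k = reach[i], reach[k]
                for j in range(n_nodes):
                    if row_k[j]:
                        row_i[j] = True
    seen: set[int] = set()
    parts = []
    for i in range(n_nodes):
        if i not in seen:
            comp = frozenset(j for j in range(n_nodes) if reach[i][j])
            seen.update(comp)
            parts.append(comp)
    return parts
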
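"""Independent brute-force oracles used only by tests.

These deliberately use the dumbest correct algorithm (repeated full passes,
from-scratch recomputation) so they share no code path with the package.
"""

from __future__ import annotations


def reachability_oracle(net, present_rxns) -> set[str]:
    """Fixed-point producibility by exhaustive re-scanning until no change."""
    currency = {m for m, rec in net.metabolites.items() if rec.is_currency}
    available = set(currency) | {net.root_met}
    while True:
        added = False
        for rid in present_rxns:
            rxn = net.reactions[rid]
            directions = [(rxn.substrate_ids, rxn.product_ids)]
            if rxn.reversible:
                directions.append((rxn.product_ids, rxn.substrate_ids))
            for subs, prods in directions:
                if all(m in available for m in subs if m not in currency):
                    for m in prods:
                        if m not in available:
                            available.add(m)
                            added = True
        if not added:
            return {m for m in available if m not in currency and m != net.root_met}


def complete_linkage_oracle(d) -> list[tuple[int, int, float]]:
    """Naive agglomeration: recompute every cluster-pair distance from scratch.

    Returns merges as (cluster id a, cluster id b, height) with leaves
    numbered 0..n-1 and new clusters n, n+1, ...; ties broken by the
    lexicographically smallest id pair.
    """
    n = len(d)
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                i, j = ids[x], ids[y]
                h = max(d[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merges.append((i, j, float(h)))
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return merges


def bh_adjust_oracle(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        q = pvalues[i] * m / rank_from_end
        running_min = min(running_min, q)
        adjusted[i] = running_min
    return adjusted
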
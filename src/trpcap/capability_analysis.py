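"""Capability matrix construction and metabolic-vs-phylogenetic structure comparison.

The capability matrix is a boolean models x metabolites table: cell (i, j) is
True when reachability over model i's matched reactions produces bioactive
metabolite j.  On top of it this module offers genus-level production
prevalence, Jaccard distances between capability profiles, a reproducible
complete-linkage dendrogram, and an entanglement score for tanglegram-style
comparison against a phylogenetic dendrogram.

Reproducibility conventions for the dendrogram (documented so outputs are
bit-for-bit stable): agglomeration ties are broken by the lowest-index cluster
pair, and leaf order places the smaller subtree first (ties by smallest leaf
index).  Entanglement is the L1 rank statistic: the mean absolute shift in
leaf positions between the two orders, normalised by the maximum attainable
total shift for n leaves (floor(n^2/2)), so 0 means identical orders and 1 a
full reversal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .reference_network import IntegrityError, ReferenceNetwork, producible_set
from .gem_mining import LINEAGE_RANKS, GemModel

__all__ = [
    "CapabilityMatrix",
    "Dendrogram",
    "build_capability_matrix",
    "genus_prevalence",
    "metabolic_distance",
    "cluster_complete",
    "entanglement",
    "tree_distance_matrix",
    "export_tanglegram",
    "save_capability",
    "load_capability",
]

_META_COLS = list(LINEAGE_RANKS) + ["source", "human_gut", "mouse_gut"]


@dataclass
class CapabilityMatrix:
    """Boolean production table plus per-model metadata.

    ``values``: DataFrame indexed by model_id, boolean columns are bioactive
    metabolite ids.  ``meta``: DataFrame on the same index with lineage ranks,
    source, and host-habitat flags.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise IntegrityError("capability values and meta have different model sets")
        self.values = self.values.astype(bool)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def host_mask(self, host: str) -> pd.Series:
        if host == "all":
            return pd.Series(True, index=self.meta.index)
        if host in ("human", "mouse"):
            return self.meta[f"{host}_gut"].astype(bool)
        raise ValueError(f"host must be 'human', 'mouse' or 'all', got {host!r}")


def build_capability_matrix(
    models: list[GemModel],
    net: ReferenceNetwork,
    mode: str = "reachability",
) -> CapabilityMatrix:
    """One row per model; cells from :func:`producible_set` over matched reactions.

    Models whose lineage lacks a genus are excluded with a warning (they
    cannot enter genus-level modelling downstream).
    """
    usable, skipped = [], []
    for m in models:
        (usable if m.genus else skipped).append(m)
    if skipped:
        warnings.warn(
            f"excluding {len(skipped)} model(s) without genus: "
            f"{[m.model_id for m in skipped][:5]}..."
        )
    columns = sorted(net.bioactive_ids)
    cache: dict[frozenset, frozenset] = {}
    rows, meta_rows, index = [], [], []
    for m in usable:
        key = m.matched_rxns
        if key not in cache:
            cache[key] = producible_set(net, key, mode=mode)
        prod = cache[key]
        rows.append([c in prod for c in columns])
        meta = {r: m.lineage[r] for r in LINEAGE_RANKS}
        meta.update(source=m.source, human_gut=m.human_gut, mouse_gut=m.mouse_gut)
        meta_rows.append(meta)
        index.append(m.model_id)
    values = pd.DataFrame(rows, index=pd.Index(index, name="model_id"), columns=columns)
    meta = pd.DataFrame(meta_rows, index=values.index)[_META_COLS]
    return CapabilityMatrix(values=values, meta=meta)


def genus_prevalence(cap: CapabilityMatrix, host: str = "all") -> pd.DataFrame:
    """Fraction of producers per genus and metabolite, optionally host-filtered."""
    mask = cap.host_mask(host)
    if not mask.any():
        warnings.warn(f"host filter {host!r} leaves zero models")
        return pd.DataFrame(columns=cap.metabolites)
    vals = cap.values.loc[mask]
    genera = cap.meta.loc[mask, "genus"]
    return vals.groupby(genera).mean().rename_axis("genus")


def metabolic_distance(cap: CapabilityMatrix, metric: str = "jaccard") -> pd.DataFrame:
    """Model x model distance on boolean capability rows.

    Jaccard by default (Hamming via ``metric="hamming"``); two all-false rows
    are at distance 0 by convention.
    """
    if len(cap.values) < 2:
        raise ValueError("metabolic_distance needs at least two models")
    if metric not in ("jaccard", "hamming"):
        raise ValueError(f"unsupported metric {metric!r}")
    x = cap.values.to_numpy(dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on 0/0 jaccard; it returns 0
        d = squareform(np.nan_to_num(pdist(x, metric=metric)))
    return pd.DataFrame(d, index=cap.values.index, columns=cap.values.index)


# ---------------------------------------------------------------------------
# Complete-linkage dendrogram (deterministic tie rules)
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    Leaves are numbered 0..n-1 in ``labels`` order; internal node n+k is
    created by the k-th entry of ``merges`` = (left id, right id, height).
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    method: str = "complete"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("dendrogram leaves must be unique")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}

    def leaf_order(self) -> list[str]:
        """Leaf labels left-to-right: smaller subtree first, ties by min leaf index."""
        if not self.merges:
            return list(self.labels)
        children = self._children()

        def leaves(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            la, lb = leaves(a), leaves(b)
            if (len(la), min(la)) > (len(lb), min(lb)):
                la, lb = lb, la
            return la + lb

        root = self.n_leaves + len(self.merges) - 1
        return [self.labels[i] for i in leaves(root)]

    def cophenetic(self) -> pd.DataFrame:
        """Matrix of merge heights at which leaf pairs first join."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
            members[n + k] = members.pop(a) + members.pop(b)
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)


def cluster_complete(dist: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of a square distance matrix.

    Ties are broken by the lowest-index cluster pair so repeated runs give
    identical merge histories.  NaN entries, asymmetry, or a non-zero
    diagonal are rejected.
    """
    d = np.asarray(dist, dtype=float)
    labels = [str(x) for x in dist.index] if isinstance(dist, pd.DataFrame) else [
        str(i) for i in range(d.shape[0])
    ]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have zero diagonal")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two observations to cluster")

    # full working matrix over up to 2n-1 cluster ids
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = d
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best = (np.inf, -1, -1)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                if big[i, j] < best[0]:
                    best = (big[i, j], i, j)
        h, i, j = best
        new = n + step
        for k in active:
            if k not in (i, j):
                big[new, k] = big[k, new] = max(big[i, k], big[j, k])
        merges.append((i, j, float(h)))
        active = [k for k in active if k not in (i, j)] + [new]
    return Dendrogram(labels=labels, merges=merges, method="complete")


def entanglement(d1: Dendrogram, d2: Dendrogram) -> float:
    """Disagreement between two dendrograms over the same leaves, in [0, 1].

    L1 convention: sum of |rank(leaf in d1) - rank(leaf in d2)| over leaves,
    divided by the maximum attainable sum floor(n^2/2).  0 for identical leaf
    orders; 1 when one order is the exact reversal of the other.
    """
    s1, s2 = set(d1.labels), set(d2.labels)
    if s1 != s2:
        raise ValueError(f"leaf sets differ: {sorted(s1 ^ s2)}")
    n = d1.n_leaves
    if n <= 1:
        return 0.0
    r1 = {lab: i for i, lab in enumerate(d1.leaf_order())}
    r2 = {lab: i for i, lab in enumerate(d2.leaf_order())}
    total = sum(abs(r1[lab] - r2[lab]) for lab in r1)
    return total / (n * n // 2)


def tree_distance_matrix(path) -> pd.DataFrame:
    """Patristic (branch-length) distances between leaves of a newick tree.

    Used to bring a user-supplied phylogeny onto the same footing as the
    metabolic distance matrix for tanglegram comparison.
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    d = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i < j:
                d[i, j] = d[j, i] = pdm.patristic_distance(ti, tj)
    return pd.DataFrame(d, index=labels, columns=labels)


def export_tanglegram(d1: Dendrogram, d2: Dendrogram, path) -> None:
    """Paired leaf-order TSV (one row per leaf with its rank in each tree)."""
    r2 = {lab: i for i, lab in enumerate(d2.leaf_order())}
    rows = [
        {"leaf": lab, "rank_left": i, "rank_right": r2[lab]}
        for i, lab in enumerate(d1.leaf_order())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Capability matrix I/O: single TSV, metadata columns then metabolite columns
# ---------------------------------------------------------------------------

def save_capability(cap: CapabilityMatrix, path) -> None:
    df = pd.concat([cap.meta, cap.values.astype(int)], axis=1)
    df.to_csv(path, sep="\t", index=True)


def load_capability(path) -> CapabilityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="model_id", keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: capability table missing columns {missing}")
    meta = df[_META_COLS].copy()
    meta["human_gut"] = meta["human_gut"].astype(str).isin({"1", "True", "true"})
    meta["mouse_gut"] = meta["mouse_gut"].astype(str).isin({"1", "True", "true"})
    for rank in LINEAGE_RANKS + ("source",):
        meta[rank] = meta[rank].astype(str)
    values = df.drop(columns=_META_COLS).astype(int).astype(bool)
    return CapabilityMatrix(values=values, meta=meta)
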
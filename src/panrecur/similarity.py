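"""Gene-based cosine similarity of cancer types and hierarchical clustering.

Each cancer type is summarized by a gene vector built from the
*pan-cancer recurrent* mutations (seen in >= 2 donors in the pooled
catalog): component g counts the distinct donors of that type carrying
at least one recurrent mutation in gene g.  Donor counts (not binary
flags, not fractions) are used so that both prevalence and cohort size
shape the vector.  Types are compared by cosine similarity — scale-free,
so a large cohort and a small cohort with proportional gene profiles
are maximally similar — and clustered agglomeratively on distance
1 - similarity.

Average linkage (UPGMA) is implemented directly rather than delegated:
the merge order is fully deterministic, breaking distance ties by the
lexicographically smallest pair of cluster label sets, so identical
inputs give byte-identical dendrograms on any platform.  At the scale of
tens of cancer types the O(n^3) agglomeration is instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Catalog, KEY_COLUMNS, MutationKey
from .recurrence import RecurrenceTable

import logging

logger = logging.getLogger("panrecur")


# ---------------------------------------------------------------------------
# Gene-by-type donor-count matrix
# ---------------------------------------------------------------------------

def pan_recurrent_set(table: RecurrenceTable) -> set[MutationKey]:
    """Mutation keys recurrent (>= 2 distinct donors) in the pooled scope."""
    rec = table.counts[table.counts["recurrence"] >= 2]
    return {
        MutationKey(r.chromosome, int(r.start), r.ref, r.alt)
        for r in rec.itertuples(index=False)
    }


def gene_donor_matrix(catalog: Catalog, recurrent: set[MutationKey]) -> pd.DataFrame:
    """Cancer-type x gene matrix of donors carrying recurrent mutations.

    Cell (t, g) counts the distinct donors of type t with at least one
    call whose key is in ``recurrent`` and whose gene is g; a donor with
    several recurrent mutations in one gene counts once.  All-zero gene
    columns are dropped; calls lacking a gene label are excluded and
    logged.
    """
    if not recurrent:
        raise ValueError("recurrent mutation set is empty")
    keys = pd.DataFrame(
        [(k.chromosome, k.start, k.ref, k.alt) for k in recurrent],
        columns=list(KEY_COLUMNS),
    )
    keys["start"] = keys["start"].astype(catalog.calls["start"].dtype)
    hits = catalog.calls.merge(keys, on=list(KEY_COLUMNS))
    n_unlabeled = int((hits["gene"] == "").sum())
    if n_unlabeled:
        logger.info("excluding %d recurrent call(s) without gene label", n_unlabeled)
        hits = hits[hits["gene"] != ""]
    if len(hits) == 0:
        raise ValueError("no recurrent call carries a gene label")
    cells = (
        hits.drop_duplicates(subset=["cancer_type", "gene", "donor_id"])
        .groupby(["cancer_type", "gene"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    # include types that have calls but no recurrent hit, as all-zero rows
    all_types = sorted(catalog.cancer_types)
    cells = cells.reindex(index=all_types, fill_value=0)
    cells = cells.loc[:, cells.sum(axis=0) > 0]
    cells.index.name = "cancer_type"
    cells.columns.name = "gene"
    return cells.astype(int)


def cosine_similarity_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity of the type vectors (rows).

    All entries lie in [0, 1] because the vectors are non-negative; the
    diagonal is exactly 1.  A type whose vector is all zero has no
    direction and is rejected by name.
    """
    values = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(values, axis=1)
    zero = norms == 0
    if zero.any():
        bad = list(matrix.index[zero])
        raise ValueError(f"zero gene vector for cancer type(s): {bad}")
    unit = values / norms[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# Agglomerative clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DendroNode:
    """A dendrogram node: a leaf (label set, height 0) or a merge."""

    labels: tuple[str, ...]  # sorted leaf labels under this node
    height: float
    children: tuple["DendroNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    root: DendroNode
    linkage: str = "average"

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.labels

    def merges(self) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
        """(left labels, right labels, height) in merge order."""
        out = []

        def walk(node: DendroNode) -> None:
            if node.is_leaf:
                return
            a, b = node.children
            walk(a)
            walk(b)
            out.append((a.labels, b.labels, node.height))

        walk(self.root)
        out.sort(key=lambda m: (m[2], m[0], m[1]))
        return out

    def first_bipartition(self) -> tuple[frozenset, frozenset]:
        a, b = self.root.children
        return frozenset(a.labels), frozenset(b.labels)

    def cophenetic(self) -> pd.DataFrame:
        """Leaf x leaf matrix of merge heights (ultrametric distances)."""
        labels = self.leaves
        idx = {l: i for i, l in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))

        def walk(node: DendroNode) -> None:
            if node.is_leaf:
                return
            a, b = node.children
            for la in a.labels:
                for lb in b.labels:
                    m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = node.height
            walk(a)
            walk(b)

        walk(self.root)
        return pd.DataFrame(m, index=labels, columns=labels)


def hierarchical_dendrogram(sim: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on distance 1 - similarity.

    Supported linkages: ``average`` (mean pairwise leaf distance between
    clusters; the default), ``single`` and ``complete``.  Ties in the
    candidate distances are broken by the lexicographically smallest
    (left, right) pair of sorted label tuples, making the merge order
    deterministic.
    """
    labels = list(sim.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 cancer types to cluster")
    if linkage not in {"average", "single", "complete"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    dist = 1.0 - sim.to_numpy(dtype=float)
    idx = {l: i for i, l in enumerate(labels)}
    clusters: list[DendroNode] = [DendroNode((l,), 0.0) for l in sorted(labels)]

    def cluster_distance(a: DendroNode, b: DendroNode) -> float:
        pair = np.array(
            [[dist[idx[x], idx[y]] for y in b.labels] for x in a.labels]
        )
        if linkage == "average":
            return float(pair.mean())
        if linkage == "single":
            return float(pair.min())
        return float(pair.max())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                left, right = sorted((a.labels, b.labels))
                cand = (cluster_distance(a, b), left, right, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        d, _, _, i, j = best
        a, b = clusters[i], clusters[j]
        left, right = sorted(((a.labels, a), (b.labels, b)))
        merged = DendroNode(
            labels=tuple(sorted(a.labels + b.labels)),
            height=float(d),
            children=(left[1], right[1]),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return Dendrogram(clusters[0], linkage=linkage)


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

def _escape_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram, decimals: int = 6) -> str:
    """Serialize under the height-halving (ultrametric) convention.

    A node merged at height h sits at depth h/2 from its leaves, so the
    cophenetic distance between two leaves equals their merge height.
    The branch length of a child is parent_height/2 - child_height/2.
    """

    def render(node: DendroNode) -> str:
        if node.is_leaf:
            return _escape_label(node.labels[0])
        parts = []
        for child in node.children:
            blen = (node.height - child.height) / 2.0
            parts.append(f"{render(child)}:{blen:.{decimals}g}")
        return "(" + ",".join(parts) + ")"

    return render(dendrogram.root) + ";"
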
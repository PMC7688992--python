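"""Gene-set enrichment and the enrichment-heatmap clustering matrix.

For each annotation term a 2x2 table is formed — differential set vs. the
rest of the background, inside vs. outside the term — and tested with a
two-tailed Fisher's exact test computed by hypergeometric point-mass
summation: the P-value is the sum of probabilities of all tables (with the
observed margins) whose point probability does not exceed the observed
table's.  P-values are Benjamini-Hochberg corrected across the terms of a
group.

For heatmaps, the term x group P-value matrix is filtered to terms with
P < alpha in at least one group, transformed to x = -log10(P), row
z-scored (population SD; constant rows flagged and set to 0) and ordered
by average-linkage (UPGMA) hierarchical clustering of the rows with
Euclidean distance.  Columns keep their input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError

GeneSetAnnotation = Mapping[str, tuple[str, Sequence[str]]]


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: term <tab> description <tab> member genes."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"malformed GMT line: {line[:80]!r}")
            out[fields[0]] = (fields[1], fields[2:])
    return out


def fisher_two_tailed(k: int, K: int, n: int, N: int) -> float:
    """Two-tailed Fisher P for drawing k term members in a size-n set.

    ``N`` background genes of which ``K`` are in the term; ``n`` genes in
    the differential set, ``k`` of them in the term.  Sums hypergeometric
    point masses over all feasible k' whose probability is at most the
    observed one (with a small relative tolerance against floating-point
    ties), the standard two-sided convention.
    """
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    observed = hypergeom.pmf(k, N, K, n)
    p = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class EnrichmentCell:
    """One term x group enrichment result."""

    term_id: str
    group_id: str
    k: int  # differential genes in the term
    n: int  # differential set size
    K: int  # term size within background
    N: int  # background size
    p: float
    q: float


def fisher_enrichment(
    de_set: Iterable[str],
    background: Iterable[str],
    annotation: GeneSetAnnotation,
    group_id: str = "default",
) -> list[EnrichmentCell]:
    """Test every annotation term for enrichment of ``de_set`` in ``background``.

    Term members outside the background are ignored; BH correction is
    applied across the terms of this group.  Raises
    :class:`~vigornet.errors.InputError` if the differential set is not a
    subset of the background.
    """
    bg = set(background)
    de = set(de_set)
    if not bg:
        raise InputError("background is empty")
    offenders = sorted(de - bg)
    if offenders:
        raise InputError(
            f"differential set contains genes outside the background: {offenders[:10]}"
        )
    N, n = len(bg), len(de)
    cells = []
    for term_id in sorted(annotation):
        _, members = annotation[term_id]
        term = set(members) & bg
        K = len(term)
        k = len(term & de)
        p = fisher_two_tailed(k, K, n, N)
        cells.append((term_id, k, K, p))
    if not cells:
        return []
    qs = multipletests([c[3] for c in cells], method="fdr_bh")[1]
    return [
        EnrichmentCell(term_id=t, group_id=group_id, k=k, n=n, K=K, N=N, p=p, q=float(q))
        for (t, k, K, p), q in zip(cells, qs)
    ]


@dataclass(frozen=True)
class HeatmapMatrix:
    """Row-clustered z-score matrix for an enrichment heatmap.

    ``values`` is the z matrix (terms x groups, rows in dendrogram order),
    ``x`` the matching -log10(P) matrix, ``linkage_matrix`` the scipy
    linkage of the rows (None when fewer than two rows), and
    ``constant_rows`` the terms whose x row had zero variance (their z row
    is all zeros by convention).
    """

    values: pd.DataFrame
    x: pd.DataFrame
    linkage_matrix: np.ndarray | None
    constant_rows: tuple[str, ...]

    def to_newick(self) -> str:
        """Newick export of the row dendrogram, branch lengths = merge heights."""
        if self.linkage_matrix is None:
            leaves = list(self.values.index)
            return f"({','.join(leaves)});" if len(leaves) > 1 else (
                f"{leaves[0]};" if leaves else ";"
            )
        tree = to_tree(self.linkage_matrix)
        # rows are stored in dendrogram order; leaves_list maps positions
        # back to the original leaf ids used inside the linkage matrix
        idx_labels = {i: term for i, term in zip(leaves_list(self.linkage_matrix),
                                                 self.values.index)}

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{idx_labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def build_heatmap_matrix(
    cells: Iterable[EnrichmentCell],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> HeatmapMatrix:
    """Assemble, filter, transform and cluster the enrichment matrix.

    Keeps terms with P < ``alpha`` in at least one group (raw P by default;
    set ``use_adjusted`` to filter and transform BH-adjusted values), takes
    x = -log10(P), z-scores each row with the population SD, and orders the
    rows by UPGMA clustering.  An empty result (no term passes) is returned
    with a warning rather than raised.
    """
    cells = list(cells)
    if not cells:
        warnings.warn("no enrichment cells supplied; empty heatmap")
        empty = pd.DataFrame()
        return HeatmapMatrix(values=empty, x=empty, linkage_matrix=None, constant_rows=())

    groups = list(dict.fromkeys(c.group_id for c in cells))  # input order
    pcol = "q" if use_adjusted else "p"
    frame = pd.DataFrame(
        [(c.term_id, c.group_id, getattr(c, pcol)) for c in cells],
        columns=["term", "group", "p"],
    )
    pmat = frame.pivot_table(index="term", columns="group", values="p").reindex(
        columns=groups
    )
    keep = (pmat < alpha).any(axis=1)
    pmat = pmat.loc[keep].sort_index()
    if pmat.empty:
        warnings.warn(f"no term enriched at P < {alpha} in any group; empty heatmap")
        empty = pd.DataFrame(columns=groups)
        return HeatmapMatrix(values=empty, x=empty, linkage_matrix=None, constant_rows=())

    x = -np.log10(pmat)
    sd = x.std(axis=1, ddof=0)
    constant = tuple(x.index[sd == 0])
    z = x.sub(x.mean(axis=1), axis=0)
    z = z.div(sd.replace(0.0, np.inf), axis=0)  # constant rows -> 0

    if len(x) >= 2:
        lm = linkage(z.to_numpy(), method="average", metric="euclidean")
        order = leaves_list(lm)
        z, x = z.iloc[order], x.iloc[order]
    else:
        lm = None
    return HeatmapMatrix(values=z, x=x, linkage_matrix=lm, constant_rows=constant)


def write_enrichment(
    cells: Iterable[EnrichmentCell], heatmap: HeatmapMatrix, outdir: str | Path
) -> None:
    """Write enrichment.tsv and linkage.nwk under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cells:
        x = float(-np.log10(c.p)) if c.p > 0 else float("inf")
        z = (
            float(heatmap.values.loc[c.term_id, c.group_id])
            if c.term_id in heatmap.values.index
            else float("nan")
        )
        rows.append(
            {"term": c.term_id, "group": c.group_id, "p": c.p, "q": c.q, "x": x, "z": z}
        )
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    (outdir / "linkage.nwk").write_text(heatmap.to_newick() + "\n")
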
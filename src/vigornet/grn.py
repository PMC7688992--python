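"""Subsample-consensus regulatory-network inference.

The compendium is normalised (FPKM -> TPM), log-transformed, row
zero-meaned and variance-filtered; genes are split into candidate
regulators ("factors") and genes whose regulators are inferred
("targets").  Thirty half-size sample subsets are drawn independently and
a sparse per-target regulator set is learned on each; edges recurring in
at least ``ceil(confidence * n_subsets)`` subset networks (18 of 30 at 60%
confidence) form the consensus network.

The per-subset learner is a deterministic greedy forward selection: for
each target, factors are added one at a time by largest residual
sum-of-squares reduction, a step being accepted only if the BIC

    m * ln(RSS / m) + (q + 1) * ln(m)

decreases (m samples in the subset, q regulators selected so far, one
parameter for the intercept).  Selection stops at no improvement or at
``max_regulators_per_target``.  Score ties are broken toward the
lexicographically smallest factor id, making the learner fully
deterministic given the subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConsensusParams
from .errors import ConfigError, InferenceError, InputError

logger = logging.getLogger(__name__)

_MIN_SUBSET_SAMPLES = 8
_TIE_RTOL = 1e-9
_COLLINEAR_TOL = 1e-10


def fpkm_to_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample (column) so its values sum to 10^6.

    FPKM already normalises by gene length, so within-sample rescaling to a
    fixed total is all that separates it from TPM.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise InputError("expression matrix contains negative values")
    sums = values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise InputError(f"zero-sum sample column(s): {list(matrix.columns[zero])}")
    return matrix / sums * 1e6


def zero_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's (row) mean; idempotent."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


def preprocess(matrix: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """FPKM -> TPM -> (optionally) log2(TPM+1) -> row zero-mean.

    ``log_transform=False`` supports compendia already assembled on a log
    scale; the variance filter's +/-1 band is only meaningful on log-like
    values.
    """
    tpm = fpkm_to_tpm(matrix)
    if log_transform:
        tpm = np.log2(tpm + 1.0)
    return zero_mean(tpm)


def retention_filter(
    zm_matrix: pd.DataFrame,
    de_union: Iterable[str],
    delta: float = 1.0,
    min_samples: int = 5,
) -> set[str]:
    """Keep genes that swing at least ``delta`` from their mean in at least
    ``min_samples`` samples *and* belong to the differential-feature union."""
    if delta <= 0:
        raise ConfigError(f"delta must be > 0, got {delta}")
    if min_samples < 1:
        raise ConfigError(f"min_samples must be >= 1, got {min_samples}")
    if zm_matrix.empty:
        return set()
    hits = (zm_matrix.abs() >= delta).sum(axis=1)
    variable = set(zm_matrix.index[hits >= min_samples])
    return variable & set(de_union)


@dataclass(frozen=True)
class RoleAssignment:
    """Factor and target gene sets for inference."""

    factors: frozenset[str]
    targets: frozenset[str]


def assign_roles(
    deg_set: Iterable[str],
    dep_gene_set: Iterable[str],
    regulator_genes: Iterable[str],
    mirna_targets: Iterable[str],
    retained: Iterable[str] | None = None,
) -> RoleAssignment:
    """Assign inference roles from the differential and annotation sets.

    Targets are the differential transcripts, the genes of differential
    proteins and the miRNA targets; factors are the differential-protein
    genes, the known regulator genes (transcription factors, modification
    enzymes) and the miRNA targets.  Both sets are intersected with the
    retained genes when a retention set is supplied.
    """
    targets = set(deg_set) | set(dep_gene_set) | set(mirna_targets)
    factors = set(dep_gene_set) | set(regulator_genes) | set(mirna_targets)
    if retained is not None:
        keep = set(retained)
        targets &= keep
        factors &= keep
    if not factors:
        raise InferenceError("no factor genes remain after intersection with retained genes")
    return RoleAssignment(factors=frozenset(factors), targets=frozenset(targets))


def _greedy_select(
    y: np.ndarray, F: np.ndarray, factor_names: Sequence[str], max_regulators: int
) -> list[tuple[str, float]]:
    """Greedy forward selection with BIC acceptance for one target.

    Returns the selected (factor, coefficient) list.  Coefficients come
    from the final joint least-squares fit.
    """
    m = y.shape[0]
    k = F.shape[1]
    # orthonormal basis of the current design (starts with the intercept)
    Q = np.full((m, 1), 1.0 / math.sqrt(m))
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    bic = m * math.log(max(rss, 1e-300) / m) + 1 * math.log(m)
    selected: list[int] = []
    available = np.ones(k, dtype=bool)

    while len(selected) < max_regulators and available.any():
        Fres = F - Q @ (Q.T @ F)
        norms2 = np.einsum("ij,ij->j", Fres, Fres)
        collinear = available & (norms2 <= _COLLINEAR_TOL * m)
        if collinear.any():
            for j in np.flatnonzero(collinear):
                logger.warning(
                    "factor %s is collinear with the selected design; skipped",
                    factor_names[j],
                )
            available &= ~collinear
            if not available.any():
                break
        proj = Fres.T @ resid
        reduction = np.where(available & (norms2 > 0), proj**2 / np.maximum(norms2, 1e-300), -np.inf)
        best = reduction.max()
        if not np.isfinite(best) or best <= 0:
            break
        # ties toward the lexicographically smallest factor id
        tied = np.flatnonzero(reduction >= best * (1 - _TIE_RTOL))
        j = min(tied, key=lambda idx: factor_names[idx])

        new_rss = rss - float(reduction[j])
        q = len(selected) + 1
        new_bic = m * math.log(max(new_rss, 1e-300) / m) + (q + 1) * math.log(m)
        if new_bic >= bic:
            break
        qvec = Fres[:, j] / math.sqrt(norms2[j])
        Q = np.hstack([Q, qvec[:, None]])
        resid = resid - qvec * (qvec @ resid)
        rss, bic = new_rss, new_bic
        selected.append(int(j))
        available[j] = False

    if not selected:
        return []
    X = np.column_stack([np.ones(m), F[:, selected]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return [(factor_names[j], float(c)) for j, c in zip(selected, coef[1:])]


def learn_subnetwork(
    zm_matrix: pd.DataFrame,
    roles: RoleAssignment,
    max_regulators_per_target: int = 5,
) -> dict[tuple[str, str], float]:
    """Infer a directed factor -> target edge set on one sample subset.

    ``zm_matrix`` holds the preprocessed expression of the subset's samples
    (genes x samples).  Returns {(factor, target): coefficient}.  A target
    never regulates itself; purely noisy targets come back empty because
    the BIC penalty rejects every candidate.
    """
    if zm_matrix.shape[1] < _MIN_SUBSET_SAMPLES:
        raise InputError(
            f"need at least {_MIN_SUBSET_SAMPLES} samples, got {zm_matrix.shape[1]}"
        )
    if not roles.factors or not roles.targets:
        raise InferenceError("both factors and targets must be nonempty")
    present = set(zm_matrix.index)
    factors = sorted(set(roles.factors) & present)
    targets = sorted(set(roles.targets) & present)
    if not factors or not targets:
        raise InferenceError("roles do not overlap the expression matrix")

    Fall = zm_matrix.loc[factors].to_numpy(dtype=float).T  # samples x factors
    edges: dict[tuple[str, str], float] = {}
    fidx = {f: i for i, f in enumerate(factors)}
    for t in targets:
        y = zm_matrix.loc[t].to_numpy(dtype=float)
        if t in fidx:
            cols = [i for f, i in fidx.items() if f != t]
            names = [f for f in factors if f != t]
            F = Fall[:, cols]
        else:
            F, names = Fall, factors
        if F.shape[1] == 0:
            continue
        for f, coef in _greedy_select(y, F, names, max_regulators_per_target):
            edges[(f, t)] = coef
    return edges


@dataclass(frozen=True)
class ConsensusNetwork:
    """Directed consensus edges with subset occurrence counts and sign.

    ``occurrence`` counts subsets (out of ``n_subsets``) containing the
    edge; ``sign`` is the sign of the mean coefficient across those
    subsets.
    """

    edges: dict[tuple[str, str], dict] = field(default_factory=dict)
    n_subsets: int = 0
    subsets: tuple[tuple[str, ...], ...] = ()

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f,
                "target": t,
                "count": rec["count"],
                "sign": rec["sign"],
            }
            for (f, t), rec in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["factor", "target", "count", "sign"])


def draw_subsets(
    n_samples: int, params: ConsensusParams
) -> list[np.ndarray]:
    """Draw ``n_subsets`` independent sample subsets without replacement
    within each subset (a sample may recur across subsets)."""
    size = int(math.floor(params.subset_fraction * n_samples))
    if size < _MIN_SUBSET_SAMPLES:
        raise ConfigError(
            f"subset_fraction {params.subset_fraction} of {n_samples} samples "
            f"gives {size} < {_MIN_SUBSET_SAMPLES} samples per subset"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(101,))
    )
    return [
        np.sort(rng.choice(n_samples, size=size, replace=False))
        for _ in range(params.n_subsets)
    ]


def apply_consensus_threshold(
    counts: dict[tuple[str, str], int],
    coef_sums: dict[tuple[str, str], float] | None,
    params: ConsensusParams,
) -> dict[tuple[str, str], dict]:
    """Keep edges whose subset occurrence reaches ``params.min_count``."""
    coef_sums = coef_sums or {}
    return {
        e: {"count": c, "sign": int(np.sign(coef_sums.get(e, 0.0)))}
        for e, c in counts.items()
        if c >= params.min_count
    }


def consensus_network(
    zm_matrix: pd.DataFrame,
    roles: RoleAssignment,
    params: ConsensusParams | None = None,
) -> ConsensusNetwork:
    """Run the learner over subsample subsets and keep recurrent edges.

    Deterministic for a fixed ``params.seed``.  Edges kept have occurrence
    >= ``params.min_count``.
    """
    params = params or ConsensusParams()
    subsets = draw_subsets(zm_matrix.shape[1], params)
    counts: dict[tuple[str, str], int] = {}
    coef_sums: dict[tuple[str, str], float] = {}
    for cols in subsets:
        sub = zm_matrix.iloc[:, cols]
        edges = learn_subnetwork(sub, roles, params.max_regulators_per_target)
        for e, coef in edges.items():
            counts[e] = counts.get(e, 0) + 1
            coef_sums[e] = coef_sums.get(e, 0.0) + coef
    kept = apply_consensus_threshold(counts, coef_sums, params)
    sample_names = list(zm_matrix.columns)
    return ConsensusNetwork(
        edges=kept,
        n_subsets=params.n_subsets,
        subsets=tuple(tuple(sample_names[i] for i in cols) for cols in subsets),
    )


def recovery_metrics(
    consensus: ConsensusNetwork, true_edges: Iterable[tuple[str, str]]
) -> dict[str, float]:
    """Precision/recall of consensus edges against a planted edge set,
    ignoring direction-irrelevant attributes (edges compared as ordered
    (factor, target) pairs)."""
    truth = set(true_edges)
    found = consensus.edge_set()
    tp = len(found & truth)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp,
            "n_inferred": len(found), "n_true": len(truth)}


def write_consensus(
    network: ConsensusNetwork, params: ConsensusParams, outdir: str | Path
) -> None:
    """Write consensus_edges.tsv and a grn_manifest.json run manifest."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network.to_frame().to_csv(outdir / "consensus_edges.tsv", sep="\t", index=False)
    manifest = {
        "n_subsets": params.n_subsets,
        "subset_fraction": params.subset_fraction,
        "confidence": params.confidence,
        "min_count": params.min_count,
        "max_regulators_per_target": params.max_regulators_per_target,
        "seed": params.seed,
        "n_edges": len(network),
        "subset_samples": [list(s) for s in network.subsets],
    }
    (outdir / "grn_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
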
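"""Seeded synthetic inputs with the structure the downstream analysis assumes.

The generator stands in for the study-scale inputs of the real analysis: a
multi-experiment expression compendium for network inference, transcript and
protein differential tables with planted crosstalk-category structure, a
scored protein-interaction edge list, a miRNA target list, and gene-set
annotations with a planted enriched term.  Ground truth (the planted
regulatory network, the planted category of every feature) is returned
alongside, so recovery can be measured exactly.

Expression model
----------------
Regulator genes ("factors") get i.i.d. standard-normal latent profiles on a
log2 scale; each planted target is a signed linear combination of its
regulators plus Gaussian noise, and unregulated genes are independent noise.
The latent matrix is shifted, exponentiated (base 2) and column-scaled to
library sizes near 10^6, yielding a nonnegative FPKM-like matrix in which
the planted effects remain recoverable by a linear learner after the
standard TPM / log / zero-mean preprocessing.

All randomness flows from ``SimConfig.seed`` through fixed per-generator
substreams, so adding one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError

# fixed substream offsets: adding a generator must not disturb the others
_STREAM_COMPENDIUM = 0
_STREAM_DIFF = 1
_STREAM_PPI = 2
_STREAM_ANNOT = 3
_STREAM_MIRNA = 4

_LOG2_BASELINE = 5.0  # latent log2 offset before exponentiation


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,))
    )


def gene_ids(cfg: SimConfig) -> list[str]:
    """Stable gene identifiers G0000..G{n-1}."""
    return [f"G{i:04d}" for i in range(cfg.n_genes)]


def factor_ids(cfg: SimConfig) -> list[str]:
    """The designated regulator genes (first ``n_factors`` identifiers)."""
    return gene_ids(cfg)[: cfg.n_factors]


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground-truth directed regulatory structure.

    ``effects`` maps each (factor, target) edge to its signed log-scale
    coefficient.  Factors may regulate other factors but never themselves.
    """

    effects: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.effects)

    def __len__(self) -> int:
        return len(self.effects)


def generate_compendium(cfg: SimConfig) -> tuple[pd.DataFrame, PlantedNetwork]:
    """Simulate the expression compendium and its planted network.

    Returns a genes x samples DataFrame (FPKM-like, or log2 values when
    ``cfg.output_scale == "log"``) and the :class:`PlantedNetwork`.
    """
    rng = _rng(cfg, _STREAM_COMPENDIUM)
    genes = gene_ids(cfg)
    factors = factor_ids(cfg)
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]

    # assign targets: draw without replacement from non-factor genes while
    # the pool lasts, so each planted target has a single regulator at the
    # default sizes; fall back to reuse (multi-regulator targets) if asked
    # for more targets than the pool holds.
    pool = list(genes[cfg.n_factors:])
    rng.shuffle(pool)
    effects: dict[tuple[str, str], float] = {}
    for f in factors:
        for _ in range(cfg.targets_per_factor):
            if pool:
                t = pool.pop()
            else:
                candidates = [g for g in genes if g != f and (f, g) not in effects]
                if not candidates:
                    break
                t = candidates[int(rng.integers(len(candidates)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[(f, t)] = sign * cfg.effect_size
    planted = PlantedNetwork(effects=effects)

    latent = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    idx = {g: i for i, g in enumerate(genes)}
    regulated = sorted({t for (_, t) in effects})
    for t in regulated:
        row = np.zeros(cfg.n_samples)
        for (f, tt), eff in effects.items():
            if tt == t:
                row += eff * latent[idx[f]]
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples) if cfg.noise_sd > 0 else 0.0
        latent[idx[t]] = row + noise

    log2_expr = latent + _LOG2_BASELINE
    fpkm = np.power(2.0, log2_expr)
    # library sizes of comparable (not identical) magnitude
    depth = 1e6 * rng.uniform(0.9, 1.1, size=cfg.n_samples)
    fpkm = fpkm / fpkm.sum(axis=0, keepdims=True) * depth

    values = np.log2(fpkm + 1.0) if cfg.output_scale == "log" else fpkm
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return expr, planted


# value bands per category; DE values are sampled clear of the thresholds
# and "unchanged" values strictly inside them, so planted categories
# round-trip exactly through the classifier.
_FC_UP = (1.5, 4.0)
_RATIO_UP = (1.45, 3.0)
_P_SIG = (1e-6, 0.04)
_P_NULL = (0.2, 0.9)
_FC_NULL = (1.0 / 1.15, 1.15)
_RATIO_NULL = (1.0 / 1.25, 1.25)


def _planted_category_assignment(cfg: SimConfig) -> list[tuple[str, int]]:
    """Deterministic (gene, category) assignment for the diff tables."""
    genes = gene_ids(cfg)
    out: list[tuple[str, int]] = []
    cursor = 0
    for cat in sorted(cfg.planted_category_counts):
        for _ in range(cfg.planted_category_counts[cat]):
            out.append((genes[cursor], cat))
            cursor += 1
    return out


def generate_diff_tables(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build transcript and protein differential tables with planted categories.

    Every planted feature appears in both tables: categories 1-4 satisfy
    both layers' differential rules, 5/6 pair a differential transcript with
    a protein ratio strictly inside (1/1.3, 1.3), and 7/8 pair a transcript
    failing the DEG rule with a differential protein — "unchanged" is
    represented explicitly, not by absence.
    """
    rng = _rng(cfg, _STREAM_DIFF)
    t_rows, p_rows = [], []
    for gene, cat in _planted_category_assignment(cfg):
        t_dir = {1: "up", 2: "down", 3: "down", 4: "up", 5: "up", 6: "down"}.get(cat)
        p_dir = {1: "up", 2: "down", 3: "up", 4: "down", 7: "up", 8: "down"}.get(cat)

        if t_dir is None:  # categories 7/8: transcript fails the DEG rule
            fc = rng.uniform(*_FC_NULL)
            adj_p = rng.uniform(*_P_NULL)
        else:
            fc = rng.uniform(*_FC_UP)
            if t_dir == "down":
                fc = 1.0 / fc
            adj_p = rng.uniform(*_P_SIG)

        if p_dir is None:  # categories 5/6: ratio inside the unchanged band
            ratio = rng.uniform(*_RATIO_NULL)
        else:
            ratio = rng.uniform(*_RATIO_UP)
            if p_dir == "down":
                ratio = 1.0 / ratio

        t_rows.append({"gene_id": gene, "fc": fc, "adj_p": adj_p})
        p_rows.append({"protein_id": f"P_{gene}", "gene_id": gene, "ratio": ratio})

    transcript = pd.DataFrame(t_rows, columns=["gene_id", "fc", "adj_p"])
    protein = pd.DataFrame(p_rows, columns=["protein_id", "gene_id", "ratio"])
    return transcript, protein


def _decode_pair(k: int, n: int) -> tuple[int, int]:
    """Map a flat index in [0, n(n-1)/2) to an unordered pair (i < j)."""
    # row i starts at offset i*n - i*(i+1)/2 in the flattened upper triangle
    i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * k)) / 2)
    j = k - (i * (2 * n - i - 1)) // 2 + i + 1
    return i, j


def generate_interaction_file(cfg: SimConfig) -> pd.DataFrame:
    """Sample a scored undirected interaction edge list.

    Unique unordered gene pairs with integer combined scores uniform over
    ``cfg.ppi_score_range`` (inclusive), mirroring a database export on the
    0-1000 confidence scale.
    """
    rng = _rng(cfg, _STREAM_PPI)
    genes = gene_ids(cfg)
    n = cfg.n_genes
    max_pairs = n * (n - 1) // 2
    picks = rng.choice(max_pairs, size=cfg.ppi_edges, replace=False)
    lo, hi = cfg.ppi_score_range
    scores = rng.integers(lo, hi + 1, size=cfg.ppi_edges)
    rows = []
    for k, s in zip(sorted(int(p) for p in picks), scores):
        i, j = _decode_pair(k, n)
        rows.append({"node_a": genes[i], "node_b": genes[j], "combined_score": int(s)})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])


def generate_mirna_targets(cfg: SimConfig) -> list[str]:
    """Pick the miRNA target gene set (default 14 genes)."""
    rng = _rng(cfg, _STREAM_MIRNA)
    genes = gene_ids(cfg)
    picks = rng.choice(cfg.n_genes, size=cfg.n_mirna_targets, replace=False)
    return [genes[i] for i in sorted(int(p) for p in picks)]


def generate_annotation_map(
    cfg: SimConfig, n_terms: int = 10, term_size: int = 20
) -> dict[str, tuple[str, list[str]]]:
    """Build term -> (description, members) annotations, GMT-writable.

    One designated term (``TERM_ENRICHED``) oversamples its members from the
    transcript-differential planted genes (categories 1-6), so enrichment of
    that gene set against the full gene background is significant by
    construction at the default sizes; the remaining terms draw members
    uniformly.
    """
    rng = _rng(cfg, _STREAM_ANNOT)
    genes = gene_ids(cfg)
    de_genes = [g for g, cat in _planted_category_assignment(cfg) if cat in (1, 2, 3, 4, 5, 6)]
    terms: dict[str, tuple[str, list[str]]] = {}
    if n_terms < 1:
        return terms

    if de_genes:
        k_de = min(int(round(term_size * 0.8)), len(de_genes))
        members = list(rng.choice(de_genes, size=k_de, replace=False))
        others = [g for g in genes if g not in set(members)]
        k_bg = min(term_size - k_de, len(others))
        if k_bg > 0:
            members += list(rng.choice(others, size=k_bg, replace=False))
        terms["TERM_ENRICHED"] = ("planted enriched term", sorted(members))

    for t in range(len(terms), n_terms):
        size = min(term_size, cfg.n_genes)
        members = sorted(rng.choice(genes, size=size, replace=False))
        terms[f"TERM_{t:03d}"] = (f"random term {t}", list(members))
    return terms


def write_gmt(annotation: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            desc, members = annotation[term]
            fh.write("\t".join([term, desc, *members]) + "\n")


def write_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input and write the full bundle under ``outdir``.

    Files: expression.tsv, transcript_de.tsv, protein_de.tsv, ppi.tsv,
    mirna_targets.txt, regulators.txt, annotations.gmt, truth_edges.tsv.
    Byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr, planted = generate_compendium(cfg)
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")

    transcript, protein = generate_diff_tables(cfg)
    paths["transcript_de"] = outdir / "transcript_de.tsv"
    transcript.to_csv(paths["transcript_de"], sep="\t", index=False, float_format="%.6g")
    paths["protein_de"] = outdir / "protein_de.tsv"
    protein.to_csv(paths["protein_de"], sep="\t", index=False, float_format="%.6g")

    ppi = generate_interaction_file(cfg)
    paths["ppi"] = outdir / "ppi.tsv"
    ppi.to_csv(paths["ppi"], sep="\t", index=False)

    targets = generate_mirna_targets(cfg)
    paths["mirna_targets"] = outdir / "mirna_targets.txt"
    paths["mirna_targets"].write_text("".join(t + "\n" for t in targets))

    paths["regulators"] = outdir / "regulators.txt"
    paths["regulators"].write_text("".join(f + "\n" for f in factor_ids(cfg)))

    annotation = generate_annotation_map(cfg)
    paths["annotations"] = outdir / "annotations.gmt"
    write_gmt(annotation, paths["annotations"])

    paths["truth_edges"] = outdir / "truth_edges.tsv"
    truth = pd.DataFrame(
        [
            {"factor": f, "target": t, "effect": e}
            for (f, t), e in sorted(planted.effects.items())
        ],
        columns=["factor", "target", "effect"],
    )
    truth.to_csv(paths["truth_edges"], sep="\t", index=False, float_format="%.6g")
    return paths
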
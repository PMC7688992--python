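"""Transcript/protein differential calling and crosstalk categorization.

A feature measured in both omic layers falls into one of eight joint
regulation categories:

===========  ============  ===========
category     transcript    protein
===========  ============  ===========
1            up            up
2            down          down
3            down          up
4            up            down
5            up            unchanged
6            down          unchanged
7            unchanged     up
8            unchanged     down
===========  ============  ===========

A feature unchanged in both layers belongs to none of the eight.  Features
quantified in only one layer are treated as *unchanged* in the missing
layer and flagged via the ``layers`` provenance column, so that categories
5-8 (typically the vast majority) are representable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import CrosstalkThresholds
from .errors import InputError

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
_STATUSES = (UP, DOWN, UNCHANGED)

#: (transcript status, protein status) -> category id; both-unchanged maps to None.
_CATEGORY_TABLE: dict[tuple[str, str], int | None] = {
    (UP, UP): 1,
    (DOWN, DOWN): 2,
    (DOWN, UP): 3,
    (UP, DOWN): 4,
    (UP, UNCHANGED): 5,
    (DOWN, UNCHANGED): 6,
    (UNCHANGED, UP): 7,
    (UNCHANGED, DOWN): 8,
    (UNCHANGED, UNCHANGED): None,
}


def call_transcript_status(
    fc: float, adj_p: float, th: CrosstalkThresholds | None = None
) -> str:
    """Call a transcript up/down/unchanged from fold-change and adjusted P.

    Up requires fc > t_fc and adj_p < t_alpha; down requires fc < 1/t_fc and
    adj_p < t_alpha.  Inequalities are strict: a feature sitting exactly on
    a threshold is unchanged.
    """
    th = th or CrosstalkThresholds()
    if fc is None or adj_p is None or math.isnan(fc) or math.isnan(adj_p):
        raise InputError("transcript record requires fc and adj_p")
    if fc <= 0:
        raise InputError(f"fold-change must be > 0, got {fc}")
    if not 0 <= adj_p <= 1:
        raise InputError(f"adj_p must be in [0, 1], got {adj_p}")
    if adj_p < th.t_alpha:
        if fc > th.t_fc:
            return UP
        if fc < 1.0 / th.t_fc:
            return DOWN
    return UNCHANGED


def call_protein_status(ratio: float, th: CrosstalkThresholds | None = None) -> str:
    """Call a protein up/down/unchanged from its quantitative ratio alone."""
    th = th or CrosstalkThresholds()
    if ratio is None or math.isnan(ratio):
        raise InputError("protein record requires a ratio")
    if ratio <= 0:
        raise InputError(f"protein ratio must be > 0, got {ratio}")
    if ratio > th.p_ratio:
        return UP
    if ratio < th.ratio_down_bound:
        return DOWN
    return UNCHANGED


def assign_category(t_status: str, p_status: str) -> int | None:
    """Map a (transcript, protein) status pair to its category (1-8) or None."""
    if t_status not in _STATUSES:
        raise InputError(f"unknown transcript status {t_status!r}")
    if p_status not in _STATUSES:
        raise InputError(f"unknown protein status {p_status!r}")
    return _CATEGORY_TABLE[(t_status, p_status)]


@dataclass(frozen=True)
class CrosstalkSummary:
    """Per-category counts plus the fraction in the discordant-layer
    categories 5-8, as a percentage rounded to one decimal."""

    counts: dict[int, int]
    total: int
    fraction_5_to_8: float  # NaN when total == 0

    def to_dict(self) -> dict:
        return {
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "total": self.total,
            "fraction_5_to_8": None
            if math.isnan(self.fraction_5_to_8)
            else self.fraction_5_to_8,
        }


def summarize_crosstalk(categories) -> CrosstalkSummary:
    """Tally category assignments (each in 1..8) into a :class:`CrosstalkSummary`."""
    counts: dict[int, int] = {}
    for c in categories:
        if c not in range(1, 9):
            raise InputError(f"category out of range 1..8: {c!r}")
        counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        frac = float("nan")
    else:
        n58 = sum(counts.get(c, 0) for c in (5, 6, 7, 8))
        frac = round(100.0 * n58 / total, 1)
    return CrosstalkSummary(counts=counts, total=total, fraction_5_to_8=frac)


def classify_crosstalk(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    th: CrosstalkThresholds | None = None,
) -> pd.DataFrame:
    """Join the two differential tables on ``gene_id`` and categorize.

    ``transcripts`` needs columns ``gene_id, fc, adj_p``; ``proteins``
    needs ``gene_id, ratio``.  Features present in only one layer receive
    status *unchanged* in the missing one.  Returns a frame with columns
    ``gene_id, t_status, p_status, category, layers`` where ``category`` is
    1..8 or <NA> and ``layers`` records which layers measured the feature
    (``both``, ``transcript_only``, ``protein_only``).
    """
    th = th or CrosstalkThresholds()
    for frame, cols, name in (
        (transcripts, ("gene_id", "fc", "adj_p"), "transcript"),
        (proteins, ("gene_id", "ratio"), "protein"),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise InputError(f"{name} table missing columns: {missing}")

    t_status = {
        r.gene_id: call_transcript_status(r.fc, r.adj_p, th)
        for r in transcripts.itertuples()
    }
    p_status = {
        r.gene_id: call_protein_status(r.ratio, th) for r in proteins.itertuples()
    }
    rows = []
    for gene in sorted(set(t_status) | set(p_status)):
        in_t, in_p = gene in t_status, gene in p_status
        ts = t_status.get(gene, UNCHANGED)
        ps = p_status.get(gene, UNCHANGED)
        rows.append(
            {
                "gene_id": gene,
                "t_status": ts,
                "p_status": ps,
                "category": assign_category(ts, ps),
                "layers": "both"
                if in_t and in_p
                else ("transcript_only" if in_t else "protein_only"),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "t_status", "p_status", "category", "layers"]
    )
    out["category"] = out["category"].astype("Int64")
    return out


def write_crosstalk(
    table: pd.DataFrame, summary: CrosstalkSummary, outdir: str | Path
) -> None:
    """Write crosstalk.tsv and crosstalk_summary.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "crosstalk.tsv", sep="\t", index=False)
    (outdir / "crosstalk_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )
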
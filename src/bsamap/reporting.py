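"""Candidate ranking and interval-based candidate-gene filtering.

Two desk steps close the mapping loop: (1) rank SNV genes by their
estimated recombination frequency to the causal locus, excluded SNVs set
aside; (2) project the best-linked markers onto a reference genome,
widen the anchor span into a search interval, and intersect the genes in
that interval with an externally computed differential-expression table
(DESeq2-style: id, log2FoldChange, padj). Differential expression is
consumed, never computed here.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "rank_by_rf",
    "define_interval",
    "candidate_filter",
]


class GenomicInterval(NamedTuple):
    """Half-open, 0-clipped base-pair interval."""

    chrom: str
    start: int
    end: int

    def __contains__(self, pos) -> bool:
        return self.start <= pos < self.end


def rank_by_rf(estimates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order RF estimates ascending by point estimate.

    Ties break by LOD descending, then id; excluded SNVs are returned
    separately. Expects columns snv_id, alpha_hat, lod and optionally
    excluded.
    """
    df = estimates.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    ranked = (df[~df["excluded"].astype(bool)]
              .sort_values(["alpha_hat", "lod", "snv_id"],
                           ascending=[True, False, True],
                           na_position="last")
              .reset_index(drop=True))
    excluded = df[df["excluded"].astype(bool)].reset_index(drop=True)
    return ranked, excluded


def define_interval(anchors: Sequence[tuple[str, int]],
                    factor: float = 3.0) -> GenomicInterval:
    """Expand the span of anchor positions by ``factor`` x span per side.

    All anchors must lie on one chromosome; the result is half-open and
    clipped at 0. ``factor`` 0 returns the anchor span itself.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two anchor positions")
    chroms = {c for c, _ in anchors}
    if len(chroms) != 1:
        raise ValueError(f"anchors span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    positions = [int(p) for _, p in anchors]
    lo, hi = min(positions), max(positions)
    span = hi - lo
    start = max(0, lo - int(round(factor * span)))
    end = hi + int(round(factor * span))
    return GenomicInterval(chrom, start, end)


def candidate_filter(genes: pd.DataFrame, interval: GenomicInterval,
                     alpha: float = 0.05) -> dict:
    """Split in-interval genes by differential-expression significance.

    ``genes`` needs columns id, chrom, pos, log2FoldChange, padj (padj may
    be missing/NaN). Returns ``{"up", "down", "not_significant",
    "not_calculated"}`` DataFrames; significance is padj < alpha, strict.
    """
    required = {"id", "chrom", "pos", "log2FoldChange", "padj"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    inside = genes[(genes["chrom"] == interval.chrom)
                   & (genes["pos"] >= interval.start)
                   & (genes["pos"] < interval.end)].copy()
    padj = pd.to_numeric(inside["padj"], errors="coerce")
    not_calc = inside[padj.isna()]
    sig = inside[padj < alpha]
    non_sig = inside[(padj >= alpha)]
    return {
        "up": sig[sig["log2FoldChange"] > 0].reset_index(drop=True),
        "down": sig[sig["log2FoldChange"] <= 0].reset_index(drop=True),
        "not_significant": non_sig.reset_index(drop=True),
        "not_calculated": not_calc.reset_index(drop=True),
    }
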
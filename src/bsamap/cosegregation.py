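"""Exact two-point linkage statistics on individual F2 genotype tables.

A codominant marker scored on an F2 population segregating a recessive
causal allele yields six counts: marker genotype (AA/Aa/aa) crossed with
phenotype class (dominant/recessive), where ``A`` is the wild-type-parent
allele, in coupling with the dominant causal allele. With recombination
frequency ``a`` between marker and causal locus the cell probabilities are

====================  =====================
dominant, AA          (1 - a^2) / 4
dominant, Aa          (1 - a + a^2) / 2
dominant, aa          a * (2 - a) / 4
recessive, AA         a^2 / 4
recessive, Aa         a * (1 - a) / 2
recessive, aa         (1 - a)^2 / 4
====================  =====================

(derived from the 16 equiprobable gamete pairings). This module estimates
``a`` by maximising the multinomial likelihood on [0, 0.5], reports the LOD
score against independence, goodness-of-fit chi-square statistics, and
builds a small linear genetic map from pairwise recombination fractions.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic_data import DOMINANT, RECESSIVE

__all__ = [
    "SegregationTable",
    "LinkageResult",
    "cell_probs",
    "phenotype_chi2",
    "joint_chi2",
    "estimate_rf_ml",
    "lod_score",
    "analyze_marker",
    "rf_from_joint_table",
    "pairwise_rf_matrix",
    "order_loci",
    "format_map",
]

LN10 = math.log(10)


class SegregationTable(NamedTuple):
    """Six counts: phenotype class x marker genotype (A = wild-type-parent allele)."""

    dom_AA: int
    dom_Aa: int
    dom_aa: int
    rec_AA: int
    rec_Aa: int
    rec_aa: int

    @property
    def total(self) -> int:
        return sum(self)

    def validate(self) -> "SegregationTable":
        if any(x < 0 or int(x) != x for x in self):
            raise ValueError(f"counts must be non-negative integers: {self}")
        if self.total == 0:
            raise ValueError("degenerate segregation table: all cells zero")
        return self


class LinkageResult(NamedTuple):
    rf: float
    lod: float          # NaN when rf = 0.5 (reported as missing)
    chi2_joint: float
    df: int = 5


def cell_probs(alpha: float) -> np.ndarray:
    """Six cell probabilities at recombination frequency alpha (coupling phase)."""
    if not 0.0 <= alpha <= 0.5:
        raise ValueError(f"alpha must be in [0, 0.5], got {alpha}")
    a = alpha
    return np.array([
        (1 - a**2) / 4,
        (1 - a + a**2) / 2,
        a * (2 - a) / 4,
        a**2 / 4,
        a * (1 - a) / 2,
        (1 - a) ** 2 / 4,
    ])


def phenotype_chi2(n_dom: int, n_rec: int) -> tuple[float, float]:
    """Goodness of fit of a dominant:recessive split to 3:1 (df = 1).

    No continuity correction. Returns (chi2, p).
    """
    total = n_dom + n_rec
    if total <= 0:
        raise ValueError("empty phenotype counts")
    expected = np.array([3 * total / 4, total / 4])
    observed = np.array([n_dom, n_rec], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    from scipy.stats import chi2 as chi2_dist

    return stat, float(chi2_dist.sf(stat, 1))


def joint_chi2(table: SegregationTable) -> float:
    """Chi-square of the six cells against joint independence.

    Expected cells are N * (3/16, 6/16, 3/16, 1/16, 2/16, 1/16): the 3:1
    phenotype ratio crossed with the 1:2:1 marker ratio.
    """
    table = SegregationTable(*table).validate()
    obs = np.array(table, dtype=float)
    exp = table.total * np.array([3, 6, 3, 1, 2, 1]) / 16
    return float(((obs - exp) ** 2 / exp).sum())


def _log_likelihood(alpha: float, table: SegregationTable) -> float:
    probs = cell_probs(alpha)
    counts = np.array(table, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    # zero cells contribute nothing even where the log diverges
    return float((counts * np.where(counts > 0, logp, 0.0)).sum())


def estimate_rf_ml(table: SegregationTable, grid_step: float = 1e-4) -> float:
    """ML recombination fraction on [0, 0.5] for a six-cell table.

    Dense-grid scan followed by bounded scalar refinement; estimates are
    capped at 0.5 (no linkage).
    """
    table = SegregationTable(*table).validate()
    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    vals = [_log_likelihood(a, table) for a in grid]
    i = int(np.argmax(vals))
    lo = max(0.0, grid[i] - grid_step)
    hi = min(0.5, grid[i] + grid_step)
    res = minimize_scalar(lambda a: -_log_likelihood(a, table),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if -res.fun >= vals[i]:
        return float(res.x)
    return float(grid[i])


def lod_score(table: SegregationTable, rf: float) -> float:
    """log10 likelihood ratio of ``rf`` against independence (0.5).

    At rf = 0.5 linkage and independence coincide; the LOD is undefined
    there and reported as NaN (printed as missing).
    """
    table = SegregationTable(*table).validate()
    if not 0.0 <= rf <= 0.5:
        raise ValueError(f"rf must be in [0, 0.5], got {rf}")
    if rf == 0.5:
        return math.nan
    return (_log_likelihood(rf, table) - _log_likelihood(0.5, table)) / LN10


def analyze_marker(table: SegregationTable) -> LinkageResult:
    """RF, LOD and joint chi-square for one marker's six-cell table."""
    table = SegregationTable(*table).validate()
    rf = estimate_rf_ml(table)
    lod = lod_score(table, rf) if rf < 0.5 else math.nan
    return LinkageResult(rf, lod, joint_chi2(table))


# ---------------------------------------------------------------------------
# pairwise recombination fractions between codominant markers


def _pair_cell_probs(alpha: float) -> np.ndarray:
    """3x3 joint genotype probabilities for two codominant loci in coupling.

    Genotypes are counts of the same parent's allele at each locus; a
    gamete is parental with probability 1 - alpha, recombinant with alpha,
    and the two gametes of a plant are independent.
    """
    g = np.array([[(1 - alpha) / 2, alpha / 2],
                  [alpha / 2, (1 - alpha) / 2]])  # gamete: [allele1][allele2]
    out = np.zeros((3, 3))
    for (a1, b1), (a2, b2) in itertools.product(
            itertools.product(range(2), repeat=2), repeat=2):
        out[a1 + a2, b1 + b2] += g[a1, b1] * g[a2, b2]
    return out


def rf_from_joint_table(table3x3: np.ndarray,
                        grid_step: float = 1e-4) -> tuple[float, float]:
    """ML recombination fraction and LOD from a 3x3 codominant F2 table."""
    obs = np.asarray(table3x3, dtype=float)
    if obs.shape != (3, 3) or (obs < 0).any():
        raise ValueError("expected a non-negative 3x3 genotype table")
    if obs.sum() == 0:
        raise ValueError("empty genotype table")

    def ll(a: float) -> float:
        with np.errstate(divide="ignore"):
            logp = np.log(_pair_cell_probs(a))
        return float((obs * np.where(obs > 0, logp, 0.0)).sum())

    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    vals = [ll(a) for a in grid]
    i = int(np.argmax(vals))
    res = minimize_scalar(lambda a: -ll(a),
                          bounds=(max(0.0, grid[i] - grid_step),
                                  min(0.5, grid[i] + grid_step)),
                          method="bounded", options={"xatol": 1e-10})
    rf = float(res.x) if -res.fun >= vals[i] else float(grid[i])
    lod = math.nan if rf >= 0.5 - 1e-9 else (ll(rf) - ll(0.5)) / LN10
    return rf, lod


def pairwise_rf_matrix(genotypes: pd.DataFrame,
                       phenotypes: pd.Series | None = None,
                       causal_name: str = "phenotype"):
    """Symmetric RF (and LOD) matrices between loci.

    ``genotypes``: plants x loci, codominant 0/1/2 codes counting copies
    of the wild-type-parent allele (the same parent at every locus —
    coupling coding). If ``phenotypes`` is given (dominant/recessive per
    plant), the causal locus enters the map through the six-cell
    dominant-phenotype model. Monomorphic loci are flagged with NaN
    entries.
    """
    loci = list(genotypes.columns)
    names = loci + ([causal_name] if phenotypes is not None else [])
    k = len(names)
    rf = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    lod = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    mono = {l for l in loci if genotypes[l].nunique() <= 1}
    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            if a in mono or b in mono:
                r, d = math.nan, math.nan
            else:
                tab = np.zeros((3, 3))
                for ga, gb in zip(genotypes[a], genotypes[b]):
                    tab[int(ga), int(gb)] += 1
                r, d = rf_from_joint_table(tab)
            rf.loc[a, b] = rf.loc[b, a] = r
            lod.loc[a, b] = lod.loc[b, a] = d
    if phenotypes is not None:
        # marker vs phenotype: genotype codes are copies of the
        # wild-type-parent allele A, so AA is code 2
        for a in loci:
            if a in mono:
                rf.loc[a, causal_name] = rf.loc[causal_name, a] = math.nan
                continue
            counts = {(cls, g): 0 for cls in (DOMINANT, RECESSIVE)
                      for g in (2, 1, 0)}
            for g, ph in zip(genotypes[a], phenotypes):
                counts[(ph, int(g))] += 1
            tab = SegregationTable(
                counts[(DOMINANT, 2)], counts[(DOMINANT, 1)], counts[(DOMINANT, 0)],
                counts[(RECESSIVE, 2)], counts[(RECESSIVE, 1)], counts[(RECESSIVE, 0)],
            )
            r = estimate_rf_ml(tab)
            rf.loc[a, causal_name] = rf.loc[causal_name, a] = r
            lod.loc[a, causal_name] = lod.loc[causal_name, a] = (
                lod_score(tab, r) if r < 0.5 else math.nan)
    return rf, lod


def order_loci(rf_matrix: pd.DataFrame, max_loci: int = 10) -> list[tuple[str, float]]:
    """Order loci to minimise the summed adjacent recombination fractions.

    Exhaustive over permutations (refused above ``max_loci``). Returns
    (locus, cumulative map position) with 1 cM = 0.01 recombination
    fraction between adjacent loci (no mapping function). Orientation is
    canonical: the first locus name sorts before the last; among equal-cost
    orders the lexicographically smallest tuple wins.
    """
    names = list(rf_matrix.index)
    if len(names) < 2:
        raise ValueError("need at least two loci to order")
    if len(names) > max_loci:
        raise ValueError(f"{len(names)} loci exceeds the exhaustive-ordering "
                         f"limit of {max_loci}")
    rf = rf_matrix.to_numpy(dtype=float)
    idx = {n: i for i, n in enumerate(names)}
    best_cost, best_order = math.inf, None
    for perm in itertools.permutations(sorted(names)):
        if perm[0] > perm[-1]:
            continue  # canonical orientation
        cost = sum(rf[idx[a], idx[b]] for a, b in zip(perm, perm[1:]))
        if cost < best_cost - 1e-12 or (
                abs(cost - best_cost) <= 1e-12 and
                (best_order is None or perm < best_order)):
            best_cost, best_order = cost, perm
    out = []
    pos = 0.0
    prev = None
    for name in best_order:
        if prev is not None:
            pos += 100.0 * rf[idx[prev], idx[name]]
        out.append((name, round(pos, 6)))
        prev = name
    return out


def format_map(ordered: list[tuple[str, float]]) -> str:
    """Plain-text diagram of a linear map: position ruler plus locus names."""
    lines = ["cM      locus", "------  -----"]
    for name, pos in ordered:
        lines.append(f"{pos:6.2f}  {name}")
    return "\n".join(lines)
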
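"""Simulation of F2 mapping populations, phenotype bulks and pooled read counts.

The generator reproduces the statistical world assumed by the pooled
recombination-frequency model in :mod:`bsamap.pooled_rf`:

* an F2 population from a biparental cross, every mutant-parent allele in
  coupling phase, no crossover interference (each inter-locus interval
  recombines independently with its stated recombination frequency);
* a recessive causal locus — a plant shows the recessive phenotype iff it
  carries two mutant-parent alleles there;
* bulks of n same-phenotype plants drawn without replacement;
* per-SNV pool read counts m out of c drawn as Binomial(c, Gamma) with
  Gamma ~ Beta(G*xi, (2n-G)*xi), where G is the number of mutant-parent
  alleles among the 2n pooled chromosomes and xi is the mixing-accuracy
  concentration; at the boundaries G in {0, 2n} the Beta degenerates to a
  point mass at G/(2n);
* optional cross-library contamination ("index hopping"): each read is
  replaced, with probability ``hop_rate``, by a read drawn from the pooled
  mutant-allele frequency of the other libraries.

Genotypes are coded 0/1/2 = copies of the mutant-parent allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

RECESSIVE = "recessive"
DOMINANT = "dominant"

__all__ = [
    "Locus",
    "CrossDesign",
    "F2Population",
    "PoolDef",
    "BulkSpec",
    "Bulk",
    "SequencingModel",
    "simulate_f2_population",
    "compose_bulks",
    "simulate_pool_reads",
    "simulate_experiment",
    "write_tables",
    "load_config",
]


@dataclass(frozen=True)
class Locus:
    """One locus on the linkage map.

    ``rf_to_previous`` is the recombination frequency to the preceding locus
    in the design's order, in [0, 0.5]; it is ignored for the first locus.
    """

    name: str
    rf_to_previous: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rf_to_previous <= 0.5:
            raise ValueError(
                f"recombination frequency must be in [0, 0.5], got "
                f"{self.rf_to_previous!r} for locus {self.name!r}"
            )


@dataclass(frozen=True)
class CrossDesign:
    """Layout of the simulated biparental F2 cross.

    All mutant-parent alleles are in coupling: the F1 carries one intact
    mutant-parent homolog and one wild-type homolog.
    """

    n_plants: int
    loci: tuple[Locus, ...]
    causal_locus: str

    def __init__(self, n_plants: int, loci: Sequence[Locus | tuple], causal_locus: str):
        loci = tuple(l if isinstance(l, Locus) else Locus(*l) for l in loci)
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        if causal_locus not in names:
            raise ValueError(f"causal locus {causal_locus!r} not among loci {names}")
        if n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        object.__setattr__(self, "n_plants", int(n_plants))
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "causal_locus", causal_locus)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]


@dataclass
class F2Population:
    """Simulated F2 plants: genotype matrix, phenotypes and provenance seed.

    ``genotypes`` is a plants x loci DataFrame of 0/1/2 mutant-parent allele
    counts; ``phenotypes`` is a Series of ``"dominant"``/``"recessive"``.
    """

    genotypes: pd.DataFrame
    phenotypes: pd.Series
    causal_locus: str
    seed: int | None = None

    @property
    def n_plants(self) -> int:
        return len(self.genotypes)


@dataclass(frozen=True)
class PoolDef:
    pool_id: str
    phenotype_class: str
    n: int

    def __post_init__(self) -> None:
        if self.phenotype_class not in (RECESSIVE, DOMINANT):
            raise ValueError(f"unknown phenotype class {self.phenotype_class!r}")
        if self.n < 1:
            raise ValueError("pool size must be >= 1")


@dataclass(frozen=True)
class BulkSpec:
    """Which bulks to compose; members are drawn without replacement."""

    pools: tuple[PoolDef, ...]

    def __init__(self, pools: Sequence[PoolDef | tuple]):
        pools = tuple(p if isinstance(p, PoolDef) else PoolDef(*p) for p in pools)
        ids = [p.pool_id for p in pools]
        if len(set(ids)) != len(ids):
            raise ValueError("pool ids must be unique")
        object.__setattr__(self, "pools", pools)


@dataclass
class Bulk:
    pool_id: str
    phenotype_class: str
    n: int
    members: list
    G: dict  # locus name -> mutant-parent allele count among 2n chromosomes


@dataclass(frozen=True)
class SequencingModel:
    """Read-count model for one sequencing library per bulk.

    xi > 0 is the mixing-accuracy concentration of the Beta mixing model;
    larger xi means tissue amounts per plant are more even. ``coverage`` is
    the per-SNV per-pool read depth c. ``hop_rate`` in [0, 1) is the
    per-read probability of being replaced by a read from the pooled
    complement libraries (index hopping).
    """

    xi: float = 10.0
    coverage: int = 100
    hop_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError("xi must be > 0")
        if not 0.0 <= self.hop_rate < 1.0:
            raise ValueError("hop_rate must be in [0, 1)")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_f2_population(design: CrossDesign, seed=None) -> F2Population:
    """Draw an F2 population under the no-interference gamete model.

    Each plant is the union of two independent gametes; along the ordered
    loci a gamete follows a Markov chain that switches parental origin
    between adjacent loci with probability equal to the stated RF.
    """
    rng = _as_rng(seed)
    n, L = design.n_plants, len(design.loci)
    # gamete origin: 1 = mutant-parent chromatid segment, 0 = wild-type
    origin = np.empty((n, 2, L), dtype=np.int8)
    origin[:, :, 0] = rng.integers(0, 2, size=(n, 2))
    for j in range(1, L):
        flip = rng.random(size=(n, 2)) < design.loci[j].rf_to_previous
        origin[:, :, j] = np.where(flip, 1 - origin[:, :, j - 1], origin[:, :, j - 1])
    geno = origin.sum(axis=1)
    genotypes = pd.DataFrame(
        geno, columns=design.locus_names,
        index=pd.RangeIndex(n, name="plant_id"),
    )
    causal = genotypes[design.causal_locus].to_numpy()
    phenotypes = pd.Series(
        np.where(causal == 2, RECESSIVE, DOMINANT),
        index=genotypes.index, name="phenotype",
    )
    prov = seed if isinstance(seed, (int, np.integer)) else None
    return F2Population(genotypes, phenotypes, design.causal_locus, seed=prov)


def compose_bulks(pop: F2Population, spec: BulkSpec, seed=None) -> list[Bulk]:
    """Assign plants to bulks without replacement within each phenotype class.

    G at each locus is the plain sum of the member genotype codes, so
    0 <= G <= 2n by construction.
    """
    rng = _as_rng(seed)
    available = {
        cls: list(pop.phenotypes.index[pop.phenotypes == cls])
        for cls in (RECESSIVE, DOMINANT)
    }
    bulks: list[Bulk] = []
    for pool in spec.pools:
        cands = available[pool.phenotype_class]
        if len(cands) < pool.n:
            raise ValueError(
                f"pool {pool.pool_id!r} needs {pool.n} {pool.phenotype_class} "
                f"plants but only {len(cands)} remain unassigned"
            )
        picked = rng.choice(len(cands), size=pool.n, replace=False)
        members = [cands[i] for i in sorted(picked)]
        for m in members:
            cands.remove(m)
        g = pop.genotypes.loc[members].sum(axis=0)
        bulks.append(Bulk(pool.pool_id, pool.phenotype_class, pool.n,
                          members, g.to_dict()))
    return bulks


def simulate_pool_reads(G: int, n: int, model: SequencingModel, seed=None,
                        background_freq: float | None = None) -> tuple[int, int]:
    """Draw (m, c) for one pool at one SNV.

    Gamma ~ Beta(G*xi, (2n-G)*xi) for 0 < G < 2n, else the point mass
    G/(2n) (the Beta's limit as one shape parameter goes to 0). m is then
    Binomial(c, Gamma). If ``hop_rate`` > 0 each read is independently
    replaced by a read of mutant-parent origin with probability
    ``background_freq`` (the complement libraries' pooled mutant fraction);
    with no background supplied hopping is a no-op.
    """
    if not 0 <= G <= 2 * n:
        raise ValueError(f"G={G} outside [0, {2 * n}]")
    rng = _as_rng(seed)
    c = int(model.coverage)
    if c == 0:
        return 0, 0
    if 0 < G < 2 * n:
        gamma = rng.beta(G * model.xi, (2 * n - G) * model.xi)
    else:
        gamma = G / (2 * n)
    m = int(rng.binomial(c, gamma))
    if model.hop_rate > 0 and background_freq is not None:
        hopped = rng.binomial(c, model.hop_rate)
        if hopped:
            # hopped reads overwrite a uniformly chosen subset of own reads
            m_kept = int(rng.hypergeometric(m, c - m, c - hopped)) if hopped < c else 0
            m = m_kept + int(rng.binomial(hopped, background_freq))
    return m, c


def simulate_experiment(design: CrossDesign, spec: BulkSpec,
                        model: SequencingModel, seed=None,
                        snvs_per_locus: int = 1) -> dict:
    """Run the full generative chain: population -> bulks -> pool read counts.

    Returns ``{"population", "bulks", "counts"}`` where ``counts`` is a long
    DataFrame (snv_id, locus, pool_id, phenotype_class, n, m, c). Each locus
    carries ``snvs_per_locus`` independent SNVs (independent read draws for
    the same underlying G). Index hopping uses, per SNV and pool, the
    coverage-weighted mutant-read fraction of all other pools as the
    background frequency.
    """
    rng = _as_rng(seed)
    pop = simulate_f2_population(design, rng)
    bulks = compose_bulks(pop, spec, rng)
    rows = []
    for locus in design.locus_names:
        for k in range(snvs_per_locus):
            snv_id = f"{locus}_snv{k}" if snvs_per_locus > 1 else locus
            raw = []
            for b in bulks:
                G = int(b.G[locus])
                c = int(model.coverage)
                if 0 < G < 2 * b.n:
                    gamma = rng.beta(G * model.xi, (2 * b.n - G) * model.xi)
                else:
                    gamma = G / (2 * b.n)
                raw.append(int(rng.binomial(c, gamma)) if c else 0)
            for i, b in enumerate(bulks):
                c = int(model.coverage)
                m = raw[i]
                if model.hop_rate > 0 and c > 0 and len(bulks) > 1:
                    other_m = sum(raw) - raw[i]
                    other_c = c * (len(bulks) - 1)
                    bg = other_m / other_c
                    hopped = int(rng.binomial(c, model.hop_rate))
                    if hopped:
                        m_kept = (int(rng.hypergeometric(m, c - m, c - hopped))
                                  if hopped < c else 0)
                        m = m_kept + int(rng.binomial(hopped, bg))
                rows.append((snv_id, locus, b.pool_id, b.phenotype_class,
                             b.n, m, c))
    counts = pd.DataFrame(
        rows, columns=["snv_id", "locus", "pool_id", "phenotype_class",
                       "n", "m", "c"],
    )
    return {"population": pop, "bulks": bulks, "counts": counts}


def write_tables(result: dict, outdir) -> None:
    """Write plants.tsv, pools.tsv and counts.tsv for an experiment result."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop: F2Population = result["population"]
    plants = pop.genotypes.copy()
    plants["phenotype"] = pop.phenotypes
    plants.to_csv(outdir / "plants.tsv", sep="\t")
    pools = pd.DataFrame(
        [(b.pool_id, b.phenotype_class, b.n, ",".join(map(str, b.members)))
         for b in result["bulks"]],
        columns=["pool_id", "phenotype_class", "n", "member_ids"],
    )
    pools.to_csv(outdir / "pools.tsv", sep="\t", index=False)
    result["counts"].to_csv(outdir / "counts.tsv", sep="\t", index=False)


def load_config(path) -> tuple[CrossDesign, BulkSpec, SequencingModel, int | None]:
    """Read a YAML simulation config.

    Keys: ``loci`` (list of {name, rf} in map order), ``n_plants``,
    ``causal_locus``, ``pools`` (list of {id, class, n}), ``xi``,
    ``coverage``, ``hop_rate``, ``seed``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    design = CrossDesign(
        n_plants=cfg["n_plants"],
        loci=[Locus(l["name"], float(l.get("rf", 0.0))) for l in cfg["loci"]],
        causal_locus=cfg["causal_locus"],
    )
    spec = BulkSpec([PoolDef(p["id"], p["class"], int(p["n"]))
                     for p in cfg["pools"]])
    model = SequencingModel(
        xi=float(cfg.get("xi", 10.0)),
        coverage=int(cfg.get("coverage", 100)),
        hop_rate=float(cfg.get("hop_rate", 0.0)),
    )
    return design, spec, model, cfg.get("seed")
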
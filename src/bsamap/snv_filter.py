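"""Variant ingestion and the three-rule SNV exclusion filter.

Called variants (VCF or an equivalent TSV) carrying per-library allele
depths are screened before linkage analysis:

1. ``qual`` — site quality below the threshold (default 20);
2. ``not_snv`` / ``novel`` — not a biallelic single-nucleotide
   substitution, or a parental origin cannot be assigned (the variant is
   not fixed for different alleles in the two parent libraries);
3. ``coverage`` — total allele depth below the threshold (default 40) in
   any library, parents and pools alike.

Rules are applied in that order and each rejected record carries exactly
one primary reason. Retained SNVs get an origin assignment — which allele
came from the mutant-line parent — and their per-pool (m, c) counts feed
:mod:`bsamap.pooled_rf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SnvRecord",
    "OriginAssignment",
    "FilterResult",
    "assign_origin",
    "filter_snvs",
    "pool_counts",
    "read_table",
    "read_vcf",
    "records_from_simulation",
]

REASON_QUAL = "qual"
REASON_NOT_SNV = "not_snv"
REASON_NOVEL = "novel"
REASON_COVERAGE = "coverage"

DEFAULT_MIN_QUAL = 20.0
DEFAULT_MIN_COV = 40
DEFAULT_HET_TOLERANCE = 0.1


@dataclass
class SnvRecord:
    """One called variant with per-library (ref, alt) allele depths."""

    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    depths: dict  # library name -> (ref_depth, alt_depth)

    @property
    def snv_id(self) -> str:
        return f"{self.contig}:{self.pos}"

    def depth(self, library: str) -> tuple[int, int]:
        try:
            return self.depths[library]
        except KeyError:
            raise ValueError(
                f"record {self.snv_id}: missing depths for library "
                f"{library!r}"
            ) from None


@dataclass(frozen=True)
class OriginAssignment:
    """Which allele each parent contributed (``"ref"`` or ``"alt"``)."""

    mutant_allele: str
    wild_allele: str


@dataclass
class FilterResult:
    retained: list  # [(SnvRecord, OriginAssignment)]
    rejected: pd.DataFrame  # columns: snv_id, reason

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.rejected)


def _parent_allele(depths: tuple[int, int], tolerance: float) -> str | None:
    """The allele a parent library is (near-)homozygous for, else None."""
    ref_d, alt_d = depths
    if ref_d < 0 or alt_d < 0:
        raise ValueError("allele depths must be non-negative")
    total = ref_d + alt_d
    if total == 0:
        return None
    minor = min(ref_d, alt_d)
    if minor / total > tolerance:
        return None  # parent looks heterozygous: variant not fixed
    return "ref" if ref_d >= alt_d else "alt"


def assign_origin(record: SnvRecord, parent_mutant: str, parent_wild: str,
                  het_tolerance: float = DEFAULT_HET_TOLERANCE) -> OriginAssignment | None:
    """Assign each allele to a parent, or None when unassignable.

    Assignable only when each parent library is consistent with
    homozygosity (minor-allele depth fraction <= ``het_tolerance``) for a
    *different* allele.
    """
    a_mut = _parent_allele(record.depth(parent_mutant), het_tolerance)
    a_wild = _parent_allele(record.depth(parent_wild), het_tolerance)
    if a_mut is None or a_wild is None or a_mut == a_wild:
        return None
    return OriginAssignment(mutant_allele=a_mut, wild_allele=a_wild)


def _is_snv(record: SnvRecord) -> bool:
    return (len(record.ref) == 1 and len(record.alt) == 1
            and "," not in record.alt
            and record.ref.upper() in "ACGT" and record.alt.upper() in "ACGT")


def filter_snvs(records: Iterable[SnvRecord], parent_mutant: str,
                parent_wild: str, libraries: Sequence[str] | None = None,
                min_qual: float = DEFAULT_MIN_QUAL,
                min_cov: int = DEFAULT_MIN_COV,
                het_tolerance: float = DEFAULT_HET_TOLERANCE) -> FilterResult:
    """Apply the three exclusion rules in fixed order (qual, type/novelty, coverage).

    ``libraries`` is the full set whose coverage must clear ``min_cov``
    (defaults to every library present on the first record). A record
    lacking depths for a required library is a hard error naming it.
    """
    records = list(records)
    if libraries is None:
        libraries = sorted(records[0].depths) if records else []
    for lib in (parent_mutant, parent_wild):
        if lib not in libraries:
            libraries = list(libraries) + [lib]
    retained: list[tuple[SnvRecord, OriginAssignment]] = []
    rejected_rows = []
    for rec in records:
        for lib in libraries:
            rec.depth(lib)  # raises naming the missing library
        if rec.qual < min_qual:
            rejected_rows.append((rec.snv_id, REASON_QUAL))
            continue
        if not _is_snv(rec):
            rejected_rows.append((rec.snv_id, REASON_NOT_SNV))
            continue
        origin = assign_origin(rec, parent_mutant, parent_wild, het_tolerance)
        if origin is None:
            rejected_rows.append((rec.snv_id, REASON_NOVEL))
            continue
        if any(sum(rec.depth(lib)) < min_cov for lib in libraries):
            rejected_rows.append((rec.snv_id, REASON_COVERAGE))
            continue
        retained.append((rec, origin))
    rejected = pd.DataFrame(rejected_rows, columns=["snv_id", "reason"])
    return FilterResult(retained, rejected)


def pool_counts(retained: Sequence, pool_libraries: Sequence[str]) -> pd.DataFrame:
    """Per-SNV, per-pool mutant-parent read counts (m of c).

    ``retained`` holds (record, origin) pairs from :func:`filter_snvs`.
    m is the mutant-parent allele's depth in the pool library and c is
    m plus the wild-type-parent allele's depth; pools with c = 0 are
    flagged uninformative.
    """
    rows = []
    for rec, origin in retained:
        for lib in pool_libraries:
            ref_d, alt_d = rec.depth(lib)
            m = alt_d if origin.mutant_allele == "alt" else ref_d
            c = ref_d + alt_d
            rows.append((rec.snv_id, lib, m, c, c == 0))
    return pd.DataFrame(rows, columns=["snv_id", "pool_id", "m", "c",
                                       "uninformative"])


# ---------------------------------------------------------------------------
# input formats


def read_table(path) -> list[SnvRecord]:
    """Read variants from a TSV with contig, pos, ref, alt, qual and
    per-library ``<lib>_ref`` / ``<lib>_alt`` depth columns."""
    df = pd.read_csv(path, sep="\t")
    fixed = {"contig", "pos", "ref", "alt", "qual"}
    missing = fixed - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    libs = sorted({c[:-4] for c in df.columns if c.endswith("_ref")})
    records = []
    for row in df.itertuples():
        depths = {}
        for lib in libs:
            depths[lib] = (int(getattr(row, f"{lib}_ref")),
                           int(getattr(row, f"{lib}_alt")))
        records.append(SnvRecord(str(row.contig), int(row.pos), str(row.ref),
                                 str(row.alt), float(row.qual), depths))
    return records


def read_vcf(path, samples: Sequence[str] | None = None) -> list[SnvRecord]:
    """Read variants with per-sample allele depths (AD) from a VCF.

    Multi-allelic sites keep their comma-joined ALT so the type filter
    rejects them with reason ``not_snv``; AD then uses the first ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    use = names if samples is None else [s for s in names if s in samples]
    idx = [names.index(s) for s in use]
    records = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{var.CHROM}:{var.POS}: VCF record lacks AD")
        depths = {}
        for s, i in zip(use, idx):
            row = ad[i]
            ref_d = int(row[0]) if row[0] >= 0 else 0
            alt_d = int(row[1]) if len(row) > 1 and row[1] >= 0 else 0
            depths[s] = (ref_d, alt_d)
        qual = float(var.QUAL) if var.QUAL is not None else 0.0
        records.append(SnvRecord(var.CHROM, var.POS, var.REF,
                                 ",".join(var.ALT), qual, depths))
    return records


def records_from_simulation(counts: pd.DataFrame, parent_mutant: str = "parentM",
                            parent_wild: str = "parentW",
                            parent_depth: int = 50,
                            qual: float = 60.0) -> list[SnvRecord]:
    """Convert a simulator counts table into variant records.

    The mutant-parent allele becomes ALT; parents receive clean homozygous
    depths. One record per SNV, depths per pool library taken from (m, c).
    """
    records = []
    for i, (snv_id, grp) in enumerate(counts.groupby("snv_id", sort=False)):
        depths = {parent_mutant: (0, parent_depth),
                  parent_wild: (parent_depth, 0)}
        for r in grp.itertuples():
            depths[str(r.pool_id)] = (int(r.c) - int(r.m), int(r.m))
        records.append(SnvRecord(str(snv_id), i + 1, "A", "G", qual, depths))
    return records
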
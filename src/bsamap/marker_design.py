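"""CAPS marker screening and coding-consequence prediction.

A CAPS (cleaved amplified polymorphic sequence) marker genotypes a PCR
amplicon by allele-specific restriction digestion: an enzyme is diagnostic
for a variant when the two parental alleles yield different fragment
patterns. Recognition motifs are given in IUPAC ambiguity code and matched
on both strands; the cut position is approximated by the motif start (true
cleavage offsets are enzyme metadata outside this screen, so fragment
lengths are pattern proxies, not gel-calibrated sizes).

:func:`variant_effect` applies a substitution or single-base deletion to a
CDS, translates to the first stop, and summarises frameshift and premature
termination — the analysis behind calling a one-base deletion a truncating
loss-of-function allele.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "EnzymeSpec",
    "AllelePair",
    "CapsHit",
    "Variant",
    "VariantEffect",
    "find_sites",
    "fragment_lengths",
    "screen_caps",
    "parse_variant",
    "apply_variant",
    "variant_effect",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: name plus IUPAC recognition motif."""

    name: str
    motif: str

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("empty recognition motif")
        bad = set(self.motif.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"invalid IUPAC characters in motif: {sorted(bad)}")


@dataclass(frozen=True)
class AllelePair:
    """Amplicon sequences of the two parental alleles."""

    seq_a: str
    seq_b: str
    variant: str | None = None

    def __post_init__(self) -> None:
        for seq in (self.seq_a, self.seq_b):
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid sequence characters: {sorted(bad)}")
        if self.seq_a.upper() == self.seq_b.upper():
            raise ValueError("allele sequences are identical")


class CapsHit(NamedTuple):
    enzyme: EnzymeSpec
    sites_a: list
    sites_b: list
    fragments_a: list
    fragments_b: list
    diagnostic: bool


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    parts = []
    for ch in motif.upper():
        exp = ambiguous_dna_values[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile(f"(?=({''.join(parts)}))", re.IGNORECASE)


def find_sites(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """1-based start positions where the motif matches either strand.

    Minus-strand sites are located by matching the reverse complement of
    the motif on the forward sequence, reported at their forward-strand
    start; a palindromic motif yields one hit per position, not two.
    """
    positions = {m.start() + 1 for m in _motif_regex(enzyme.motif).finditer(seq)}
    rc = str(Seq(enzyme.motif.upper()).reverse_complement())
    positions |= {m.start() + 1 for m in _motif_regex(rc).finditer(seq)}
    return sorted(positions)


def fragment_lengths(seq: str, sites: Sequence[int]) -> list[int]:
    """Fragment lengths when cutting immediately before each site start."""
    cuts = sorted({p - 1 for p in sites if 0 < p - 1 < len(seq)})
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def screen_caps(pair: AllelePair, panel: Sequence[EnzymeSpec]) -> list[CapsHit]:
    """Screen an enzyme panel for differential digestion of the two alleles.

    An enzyme is diagnostic iff the *multiset* of fragment lengths differs
    between alleles — stricter than a site-count comparison, and sensitive
    to a deletion shifting a downstream site.
    """
    hits = []
    for enz in panel:
        sa = find_sites(pair.seq_a, enz)
        sb = find_sites(pair.seq_b, enz)
        fa = fragment_lengths(pair.seq_a, sa)
        fb = fragment_lengths(pair.seq_b, sb)
        hits.append(CapsHit(enz, sa, sb, fa, fb,
                            Counter(fa) != Counter(fb)))
    return hits


# ---------------------------------------------------------------------------
# coding consequences


class Variant(NamedTuple):
    """Minimal HGVS-like CDS variant: c.<REF><POS>del or c.<REF><POS><ALT>."""

    kind: str  # "del" or "sub"
    pos: int   # 1-based CDS coordinate
    ref: str
    alt: str | None = None


class VariantEffect(NamedTuple):
    protein_ref: str
    protein_mut: str
    mutant_length: int
    n_erroneous: int       # mutant residues after the divergence point
    frameshift: bool
    premature_stop: bool


_VARIANT_RE = re.compile(r"^c\.([ACGT])(\d+)(del|[ACGT])$", re.IGNORECASE)


def parse_variant(text: str) -> Variant:
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse variant {text!r}; expected e.g. "
                         f"'c.C319del' or 'c.C319T'")
    ref, pos, tail = m.group(1).upper(), int(m.group(2)), m.group(3)
    if tail.lower() == "del":
        return Variant("del", pos, ref)
    return Variant("sub", pos, ref, tail.upper())


def apply_variant(cds: str, variant: Variant | str) -> str:
    if isinstance(variant, str):
        variant = parse_variant(variant)
    cds = cds.upper()
    if not 1 <= variant.pos <= len(cds):
        raise ValueError(f"position {variant.pos} outside CDS of length {len(cds)}")
    if cds[variant.pos - 1] != variant.ref:
        raise ValueError(
            f"reference base mismatch at position {variant.pos}: CDS has "
            f"{cds[variant.pos - 1]!r}, variant states {variant.ref!r}")
    i = variant.pos - 1
    if variant.kind == "del":
        return cds[:i] + cds[i + 1:]
    return cds[:i] + variant.alt + cds[i + 1:]


def _translate_to_stop(cds: str) -> str:
    trimmed = cds[:len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def variant_effect(cds: str, variant: Variant | str) -> VariantEffect:
    """Protein-level consequence of a CDS substitution or 1-bp deletion.

    The reference CDS must be a whole number of codons. Premature
    termination means the mutant translation ends before the residue
    aligned to the reference stop — by an earlier in-frame stop codon, or
    by running out of frame-shifted sequence with altered residues.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("reference CDS length must be divisible by 3")
    if isinstance(variant, str):
        variant = parse_variant(variant)
    prot_ref = _translate_to_stop(cds)
    mut_cds = apply_variant(cds, variant)
    prot_mut = _translate_to_stop(mut_cds)
    frameshift = variant.kind == "del"
    # first residue where the proteins diverge
    div = next((i for i, (a, b) in enumerate(zip(prot_ref, prot_mut))
                if a != b), min(len(prot_ref), len(prot_mut)))
    n_err = max(0, len(prot_mut) - div)
    if len(prot_mut) < len(prot_ref):
        premature = True
    elif prot_mut == prot_ref:
        premature = False
    else:
        # same length or longer but altered tail: premature only if the
        # mutant lost its stop codon while encoding erroneous residues
        mut_has_stop = "*" in Seq(mut_cds[:len(mut_cds) - len(mut_cds) % 3]
                                  ).translate()
        premature = frameshift and n_err > 0 and not mut_has_stop
    return VariantEffect(prot_ref, prot_mut, len(prot_mut), n_err,
                         frameshift, premature)
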
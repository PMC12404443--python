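"""Missense-variant tables: parsing, per-position spectra, numbering maps.

Population databases such as gnomAD export one row per nucleotide variant
with a protein consequence in HGVS p. notation (``p.Met309Val``) and an
allele count.  This module aggregates those rows into per-residue *variant
spectra* — for each position, the set of alternate amino acids observed in
the population and their summed allele counts.  "Variant types" are distinct
alternate amino acids, irrespective of the underlying nucleotide change;
several nucleotide variants encoding the same substitution are summed,
never deduplicated.

Numbering conventions differ between orthologs (human TRPV1 M309 is rat
TRPV1 M308); :class:`NumberingMap` applies a constant signed offset to move
source positions onto the reference numbering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    ConsequenceParseError,
    EmptySpectrumError,
    NotMissenseError,
    NumberingOutOfRangeError,
    ReferenceMismatchError,
    UnknownAminoAcidError,
)

logger = logging.getLogger(__name__)

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}
CANONICAL_AA = frozenset(AA_ONE_TO_THREE)

#: three-letter tokens that mark a consequence as not missense
_NON_MISSENSE = {"Ter", "Sec", "Pyl", "Xaa"}

_HGVS_P = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")


@dataclass(frozen=True)
class MissenseVariant:
    """One amino-acid substitution with its population allele count."""

    ref_aa: str
    position: int
    alt_aa: str
    allele_count: int
    source_release: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa not in CANONICAL_AA or self.alt_aa not in CANONICAL_AA:
            raise UnknownAminoAcidError(
                f"non-canonical amino acid in {self.ref_aa}/{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise NotMissenseError(f"synonymous change at {self.position}")
        if self.position < 1:
            raise NumberingOutOfRangeError(f"position {self.position} < 1")
        if self.allele_count < 0:
            raise ValueError(f"negative allele count {self.allele_count}")


@dataclass
class VariantSpectrum:
    """Per-position map of alternate amino acids to summed allele counts."""

    position: int
    ref_aa: str
    counts: dict[str, int] = field(default_factory=dict)

    def total_alleles(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class NumberingMap:
    """Constant signed offset between two residue-numbering conventions."""

    offset: int = 0
    source_label: str = "source"
    reference_label: str = "reference"

    def inverse(self) -> "NumberingMap":
        return NumberingMap(-self.offset, self.reference_label, self.source_label)


#: human TRPV1 → rat TRPV1 over the ankyrin repeat domain (M309 → M308)
HUMAN_TO_RAT_TRPV1 = NumberingMap(-1, "human TRPV1", "rat TRPV1")


def parse_protein_consequence(hgvs_p: str) -> tuple[str, int, str]:
    """Parse an HGVS protein consequence into ``(ref_aa, position, alt_aa)``.

    Only true missense consequences are accepted; synonymous changes,
    stop gains (``Ter``), frameshifts and any other non-substitution
    consequence raise a distinct error.

    >>> parse_protein_consequence("p.Met309Val")
    ('M', 309, 'V')
    """
    s = hgvs_p.strip()
    if "fs" in s or "del" in s or "ins" in s or "dup" in s or s.endswith("="):
        raise NotMissenseError(f"not a substitution: {hgvs_p!r}")
    m = _HGVS_P.match(s)
    if not m:
        raise ConsequenceParseError(f"malformed HGVS p. string: {hgvs_p!r}")
    ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
    for code in (ref3, alt3):
        if code in _NON_MISSENSE:
            raise NotMissenseError(f"nonsense/non-missense code {code!r} in {hgvs_p!r}")
        if code not in AA_THREE_TO_ONE:
            raise UnknownAminoAcidError(f"unknown residue code {code!r} in {hgvs_p!r}")
    ref, alt = AA_THREE_TO_ONE[ref3], AA_THREE_TO_ONE[alt3]
    if ref == alt:
        raise NotMissenseError(f"synonymous consequence {hgvs_p!r}")
    return ref, pos, alt


def format_protein_consequence(ref_aa: str, position: int, alt_aa: str) -> str:
    """Inverse of :func:`parse_protein_consequence` (``(M, 309, V)`` → ``p.Met309Val``)."""
    return f"p.{AA_ONE_TO_THREE[ref_aa]}{position}{AA_ONE_TO_THREE[alt_aa]}"


def map_numbering(position: int, numbering: NumberingMap) -> int:
    """Apply a numbering offset; positions below 1 are rejected."""
    mapped = position + numbering.offset
    if mapped < 1:
        raise NumberingOutOfRangeError(
            f"{numbering.source_label} position {position} maps to {mapped} < 1"
        )
    return mapped


def build_spectra(
    variants: list[MissenseVariant],
    numbering: NumberingMap = NumberingMap(0),
) -> dict[int, VariantSpectrum]:
    """Aggregate variants into per-position spectra in reference numbering.

    Allele counts of identical ``(position, alt_aa)`` pairs are summed.
    Zero-count alleles are dropped from the spectra so that every stored
    count is ≥ 1.  Conflicting reference amino acids at one mapped
    position raise :class:`ReferenceMismatchError`.
    """
    spectra: dict[int, VariantSpectrum] = {}
    for v in variants:
        pos = map_numbering(v.position, numbering)
        spec = spectra.get(pos)
        if spec is None:
            spec = spectra[pos] = VariantSpectrum(pos, v.ref_aa)
        elif spec.ref_aa != v.ref_aa:
            raise ReferenceMismatchError(
                f"position {pos}: reference {spec.ref_aa} vs {v.ref_aa}"
            )
        if v.allele_count > 0:
            spec.counts[v.alt_aa] = spec.counts.get(v.alt_aa, 0) + v.allele_count
    # drop positions whose every row had allele_count == 0
    return {p: s for p, s in spectra.items() if s.counts}


def variant_type_count(spectrum: VariantSpectrum) -> int:
    """Number of distinct alternate amino acids observed at the position."""
    return sum(1 for c in spectrum.counts.values() if c >= 1)


def normalized_spectrum(spectrum: VariantSpectrum) -> dict[str, float]:
    """Counts divided by the most common alternate's count (max maps to 1.0)."""
    if not spectrum.counts:
        raise EmptySpectrumError(f"empty spectrum at position {spectrum.position}")
    top = max(spectrum.counts.values())
    return {aa: c / top for aa, c in spectrum.counts.items()}


def residue_class_spectrum(
    spectra: dict[int, VariantSpectrum],
    sequence: str,
    start: int,
    residue_class: str,
    pos_range: tuple[int, int],
) -> tuple[VariantSpectrum, list[int]]:
    """Aggregate spectra over all residues of one type in a range.

    ``sequence`` is one-letter, numbered from ``start``.  Returns the summed
    spectrum (``position`` set to 0, a sentinel for "aggregate") and the list
    of positions whose sequence letter equals ``residue_class``.
    """
    lo, hi = pos_range
    if lo < start or hi > start + len(sequence) - 1 or lo > hi:
        raise NumberingOutOfRangeError(
            f"range {pos_range} outside sequence [{start}, {start + len(sequence) - 1}]"
        )
    positions = [
        p for p in range(lo, hi + 1) if sequence[p - start] == residue_class
    ]
    agg = VariantSpectrum(0, residue_class)
    for p in positions:
        spec = spectra.get(p)
        if spec is None:
            continue
        for aa, c in spec.counts.items():
            agg.counts[aa] = agg.counts.get(aa, 0) + c
    return agg, positions


# --- tabular I/O ----------------------------------------------------------

def read_variant_csv(
    path,
    consequence_column: str = "Protein Consequence",
    allele_count_column: str = "Allele Count",
    source_release: str = "",
) -> list[MissenseVariant]:
    """Read a gnomAD-style CSV export, skipping unparseable rows.

    Rows whose consequence is not a missense substitution (stop gains,
    frameshifts, synonymous changes) or cannot be parsed are skipped and
    tallied in the log.  Rows lacking an allele count default to 1 with a
    logged warning.
    """
    df = pd.read_csv(path)
    for col in (consequence_column,):
        if col not in df.columns:
            raise ConsequenceParseError(f"column {col!r} not in {list(df.columns)}")
    variants: list[MissenseVariant] = []
    skipped = 0
    defaulted = 0
    for _, row in df.iterrows():
        try:
            ref, pos, alt = parse_protein_consequence(str(row[consequence_column]))
        except ConsequenceParseError:
            skipped += 1
            continue
        ac = row.get(allele_count_column)
        if ac is None or pd.isna(ac):
            ac = 1
            defaulted += 1
        variants.append(MissenseVariant(ref, pos, alt, int(ac), source_release))
    if skipped:
        logger.info("skipped %d non-missense/unparseable rows", skipped)
    if defaulted:
        logger.warning("%d rows lacked an allele count; defaulted to 1", defaulted)
    return variants


def spectra_to_frame(spectra: dict[int, VariantSpectrum]) -> pd.DataFrame:
    """Long-format table: one row per (position, alt_aa) with allele count."""
    rows = [
        (s.position, s.ref_aa, aa, c)
        for s in spectra.values()
        for aa, c in sorted(s.counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["position", "ref_aa", "alt_aa", "allele_count"]
    ).sort_values(["position", "alt_aa"], ignore_index=True)


def spectra_summary_frame(spectra: dict[int, VariantSpectrum]) -> pd.DataFrame:
    """Per-position summary: number of variant types and total alleles."""
    rows = [
        (s.position, s.ref_aa, variant_type_count(s), s.total_alleles())
        for s in sorted(spectra.values(), key=lambda s: s.position)
    ]
    return pd.DataFrame(
        rows, columns=["position", "ref_aa", "n_types", "total_alleles"]
    )
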
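"""Mapping coding-sequence substitutions (HGVS c.) to protein changes (HGVS p.).

The clinical nomenclature for the FBP1 variants handled here is the simple
substitution grammar only: ``c.<pos><ref>><alt>`` on the coding sequence and
``p.<aa><pos><aa>`` on the protein, e.g. ``c.491G>A`` / ``p.G164D``.
Deletions, insertions and splice-site notation are explicitly unsupported and
raise rather than being silently misparsed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.SeqIO import parse as _fasta_parse

from .errors import RefMismatchError, UnsupportedNotationError

_DNA = {"A", "C", "G", "T"}

# p. grammar accepts one-letter or three-letter amino-acid codes.
_CDS_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_PROT1_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")
_PROT3_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
# notation we recognise but do not support (reported, never guessed at)
_UNSUPPORTED_HINTS = ("del", "ins", "dup", "fs", "*", "+", "-", "_", "=", "ext")


@dataclass(frozen=True)
class CdsSubstitution:
    """A single-base substitution in 1-based coding-sequence coordinates."""

    cds_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ValueError(f"cds_pos must be >= 1, got {self.cds_pos}")
        if self.ref_base not in _DNA or self.alt_base not in _DNA:
            raise ValueError(f"bases must be A/C/G/T: {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base are identical")

    def __str__(self) -> str:
        return f"c.{self.cds_pos}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class MissenseMutation:
    """An amino-acid substitution, e.g. G164D."""

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.mut_aa:
            raise ValueError("missense requires wt_aa != mut_aa")

    @property
    def label(self) -> str:
        """Bare panel-style label, e.g. ``G164D``."""
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def __str__(self) -> str:
        return f"p.{self.label}"


@dataclass(frozen=True)
class TranslationOutcome:
    """Result of applying a CDS substitution: missense, synonymous or nonsense."""

    kind: str  # "missense" | "synonymous" | "nonsense"
    wt_aa: str
    position: int
    mut_aa: str  # "*" for nonsense
    mutation: MissenseMutation | None


def codon_index(cds_pos: int) -> int:
    """Protein residue index containing coding-sequence position ``cds_pos``.

    c. numbering starts at the A of the initiator ATG, so residue i spans
    coding positions 3i-2..3i and the map is ceil(cds_pos / 3); e.g. c.491
    falls in codon 164.
    """
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)


def apply_cds_substitution(
    cds: str,
    sub: CdsSubstitution,
    table=standard_dna_table,
) -> TranslationOutcome:
    """Translate the codon affected by ``sub`` before and after the change.

    ``cds`` must be a complete in-frame coding sequence (length divisible by
    3).  The stated reference base is checked against the sequence; a mismatch
    is a hard error naming both bases, since it almost always means the wrong
    transcript was supplied.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if sub.cds_pos > len(cds):
        raise IndexError(f"c.{sub.cds_pos} beyond CDS of length {len(cds)}")
    found = cds[sub.cds_pos - 1]
    if found != sub.ref_base:
        raise RefMismatchError(
            f"reference mismatch at c.{sub.cds_pos}: HGVS says {sub.ref_base}, "
            f"CDS has {found}"
        )

    aa_pos = codon_index(sub.cds_pos)
    start = 3 * (aa_pos - 1)
    codon = cds[start : start + 3]
    offset = (sub.cds_pos - 1) % 3
    mut_codon = codon[:offset] + sub.alt_base + codon[offset + 1 :]

    wt_aa = _translate_codon(codon, table)
    mut_aa = _translate_codon(mut_codon, table)

    if wt_aa == mut_aa:
        return TranslationOutcome("synonymous", wt_aa, aa_pos, mut_aa, None)
    if mut_aa == "*":
        return TranslationOutcome("nonsense", wt_aa, aa_pos, "*", None)
    return TranslationOutcome(
        "missense", wt_aa, aa_pos, mut_aa, MissenseMutation(wt_aa, aa_pos, mut_aa)
    )


def _translate_codon(codon: str, table) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def parse_hgvs(s: str) -> CdsSubstitution | MissenseMutation:
    """Parse a simple-substitution HGVS string (whitespace-tolerant).

    Accepts ``c.491G>A`` (also ``c.491G > A``), ``p.G164D`` and three-letter
    protein notation ``p.Gly164Asp``.  Anything else in the HGVS universe —
    ``c.960-961insG``, deletions, frameshifts — raises
    :class:`UnsupportedNotationError`.
    """
    compact = re.sub(r"\s+", "", s)
    if m := _CDS_RE.match(compact):
        return CdsSubstitution(int(m.group(1)), m.group(2), m.group(3))
    if m := _PROT1_RE.match(compact):
        return MissenseMutation(m.group(1), int(m.group(2)), m.group(3))
    if m := _PROT3_RE.match(compact):
        wt = protein_letters_3to1.get(m.group(1))
        mut = protein_letters_3to1.get(m.group(3))
        if wt is None or mut is None:
            raise UnsupportedNotationError(f"unknown amino-acid code in {s!r}")
        return MissenseMutation(wt, int(m.group(2)), mut)
    raise UnsupportedNotationError(
        f"{s!r} is not a simple c. or p. substitution"
        + (
            " (indel/splice/frameshift notation is out of scope)"
            if any(h in compact for h in _UNSUPPORTED_HINTS)
            else ""
        )
    )


def format_hgvs(obj: CdsSubstitution | MissenseMutation) -> str:
    """Canonical one-letter formatting; inverse of :func:`parse_hgvs`."""
    return str(obj)


def read_cds_fasta(path: str | Path) -> str:
    """First record of a FASTA file as an uppercase DNA string."""
    records = list(_fasta_parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq).upper().replace("U", "T")
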
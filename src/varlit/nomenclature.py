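"""Variant nomenclature: parsing protein substitutions and generating synonyms.

A single amino-acid substitution is written in the literature in many surface
dialects — one-letter (``V600E``), three-letter (``Val600Glu``), HGVS protein
level with or without parentheses (``p.V600E``, ``p.(Val600Glu)``), arrow
colloquialisms (``Val600→Glu``, ``600 V→E``) and, when the coding sequence is
known, at the transcript level as a coding-DNA substitution (``c.1799T>A`` or
the spaced ``1799 T > A``).  This module parses the protein-level dialects into
a canonical :class:`ProteinVariant` and expands a variant back into the full
set of surface forms, optionally back-translating through a registered CDS to
enumerate every single-nucleotide substitution consistent with the amino-acid
change.

Coordinate conventions: protein positions are 1-based codon indices; CDS
positions are 1-based nucleotides, so codon *n* spans CDS positions
``3n-2 .. 3n``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "AA_1TO3",
    "AA_3TO1",
    "CdnaVariant",
    "CodonMismatchError",
    "ProteinVariant",
    "SynonymSet",
    "VariantParseError",
    "apply_cdna",
    "cdna_synonyms",
    "parse_variant",
    "protein_synonyms",
    "read_cds_fasta",
    "render_cdna",
    "translate_codon",
]

MAX_SYNONYMS = 50

# The 20 standard amino acids.
AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA_3TO1 = {three.lower(): one for one, three in AA_1TO3.items()}

_STANDARD_TABLE = unambiguous_dna_by_id[1]
#: sense codon -> one-letter amino acid (stop codons excluded)
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
NUCLEOTIDES = "ACGT"

_STOP_CODES = {"ter", "x", "*", "stop"}


class VariantParseError(ValueError):
    """A variant mention could not be parsed as a protein substitution."""


class CodonMismatchError(ValueError):
    """The CDS codon does not encode the variant's stated reference residue."""


@dataclass(frozen=True, order=True)
class ProteinVariant:
    """A single amino-acid substitution, canonically in one-letter form."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA_1TO3:
                raise VariantParseError(f"not a standard amino acid: {aa!r}")
        if self.position < 1:
            raise VariantParseError(f"protein position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise VariantParseError(
                f"not a substitution: reference and alternate residue are both {self.ref_aa!r}"
            )

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def three_letter(self) -> str:
        return f"{AA_1TO3[self.ref_aa]}{self.position}{AA_1TO3[self.alt_aa]}"


@dataclass(frozen=True, order=True)
class CdnaVariant:
    """A single-nucleotide substitution in CDS coordinates (1-based)."""

    position: int
    ref_nt: str
    alt_nt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"CDS position must be >= 1, got {self.position}")
        for nt in (self.ref_nt, self.alt_nt):
            if nt not in NUCLEOTIDES:
                raise ValueError(f"not a nucleotide: {nt!r}")
        if self.ref_nt == self.alt_nt:
            raise ValueError("not a substitution: identical nucleotides")

    def __str__(self) -> str:
        return render_cdna(self)


@dataclass(frozen=True)
class SynonymSet:
    """The ordered surface forms generated for one protein variant."""

    canonical: ProteinVariant
    surface_forms: tuple[str, ...]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("none", "basic", "all"):
            raise ValueError(f"unknown synonym mode: {self.mode!r}")
        if len(self.surface_forms) > MAX_SYNONYMS:
            raise ValueError("synonym set exceeds the 50-form cap")
        if len(set(self.surface_forms)) != len(self.surface_forms):
            raise ValueError("duplicate surface forms")

    def __iter__(self):
        return iter(self.surface_forms)

    def __len__(self) -> int:
        return len(self.surface_forms)

    def __contains__(self, form: str) -> bool:
        return form in self.surface_forms


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

_ARROW = r"(?:→|->)"
# p.Val600Glu / p.(V600E) / Val600Glu / V600E / Val600→Glu and mixtures
_SUB_RE = re.compile(
    r"^(?:p\.)?(\()?([A-Za-z]{3}|[A-Za-z*])(\d+)\s*" + _ARROW + r"?\s*([A-Za-z]{3}|[A-Za-z*])(\))?$"
)
# colloquial "600 V→E"
_POSFIRST_RE = re.compile(r"^(\d+)\s*([A-Za-z*])\s*" + _ARROW + r"\s*([A-Za-z*])$")


def _decode_residue(code: str) -> str:
    """Map a 1- or 3-letter residue code to its one-letter form."""
    if code.lower() in _STOP_CODES:
        raise VariantParseError(
            f"stop-codon / termination code {code!r}: only substitutions between "
            "the 20 standard amino acids are supported"
        )
    if len(code) == 3:
        try:
            return AA_3TO1[code.lower()]
        except KeyError:
            raise VariantParseError(f"unknown three-letter residue code: {code!r}") from None
    one = code.upper()
    if one not in AA_1TO3:
        raise VariantParseError(f"unknown residue code: {code!r}")
    return one


def parse_variant(mention: str) -> ProteinVariant:
    """Parse a protein-substitution mention into a :class:`ProteinVariant`.

    Accepts one-letter (``V600E``), three-letter (``Val600Glu``,
    case-insensitive), HGVS-prefixed (``p.V600E``, ``p.(Pro871Leu)``) and
    arrow dialects (``Val600→Glu``, ``600 V->E``).  Coding-DNA descriptors
    (``c.1799T>A``) describe the transcript level and are rejected here.
    """
    if not mention or not mention.strip():
        raise VariantParseError("empty variant mention")
    text = mention.strip()
    if re.match(r"^c\.", text, flags=re.IGNORECASE):
        raise VariantParseError(
            f"coding-DNA descriptor {text!r}: expected a protein-level substitution"
        )
    m = _SUB_RE.match(text)
    if m:
        lpar, ref, pos, alt, rpar = m.groups()
        if bool(lpar) != bool(rpar):
            raise VariantParseError(f"unbalanced parentheses in {text!r}")
        # bare 1-letter forms must be uppercase to avoid reading e.g. "v600e"
        # ambiguously; 3-letter codes are matched case-insensitively
        for code in (ref, alt):
            if len(code) == 1 and not (code.isupper() or code == "*"):
                raise VariantParseError(f"lower-case one-letter residue code in {text!r}")
        return ProteinVariant(_decode_residue(ref), int(pos), _decode_residue(alt))
    m = _POSFIRST_RE.match(text)
    if m:
        pos, ref, alt = m.groups()
        return ProteinVariant(_decode_residue(ref), int(pos), _decode_residue(alt))
    raise VariantParseError(f"unparseable variant mention: {text!r}")


# --------------------------------------------------------------------------
# Coding-DNA back-translation
# --------------------------------------------------------------------------

def translate_codon(codon: str) -> Optional[str]:
    """One-letter residue for a sense codon, ``None`` for a stop codon."""
    codon = codon.upper()
    if len(codon) != 3 or any(nt not in NUCLEOTIDES for nt in codon):
        raise ValueError(f"not a codon: {codon!r}")
    return CODON_TO_AA.get(codon)


def cdna_synonyms(v: ProteinVariant, cds: str) -> list[CdnaVariant]:
    """Enumerate the single-nucleotide CDS substitutions realizing ``v``.

    The codon at ``v.position`` must translate to ``v.ref_aa``; every one of
    its nine single-nucleotide edits whose mutated codon translates to
    ``v.alt_aa`` is returned, in CDS-position order.
    """
    cds = cds.strip().upper()
    start = 3 * (v.position - 1)
    if len(cds) < start + 3:
        raise IndexError(
            f"CDS of length {len(cds)} too short for codon {v.position} "
            f"(needs >= {start + 3} nt)"
        )
    codon = cds[start:start + 3]
    observed = translate_codon(codon)
    if observed != v.ref_aa:
        raise CodonMismatchError(
            f"codon {v.position} ({codon}) encodes {observed!r}, not the "
            f"reference residue {v.ref_aa!r} of {v}"
        )
    out: list[CdnaVariant] = []
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            mutated = codon[:i] + nt + codon[i + 1:]
            if CODON_TO_AA.get(mutated) == v.alt_aa:
                out.append(CdnaVariant(start + i + 1, codon[i], nt))
    return out


def apply_cdna(cds: str, cv: CdnaVariant) -> str:
    """Apply a CDS substitution, checking the reference nucleotide."""
    cds = cds.strip().upper()
    i = cv.position - 1
    if i >= len(cds):
        raise IndexError(f"CDS position {cv.position} beyond sequence of length {len(cds)}")
    if cds[i] != cv.ref_nt:
        raise CodonMismatchError(
            f"CDS position {cv.position} is {cds[i]!r}, not {cv.ref_nt!r}"
        )
    return cds[:i] + cv.alt_nt + cds[i + 1:]


def render_cdna(cv: CdnaVariant, spaced: bool = False) -> str:
    """Render compact HGVS (``c.1799T>A``) or the spaced dialect (``1799 T > A``)."""
    if spaced:
        return f"{cv.position} {cv.ref_nt} > {cv.alt_nt}"
    return f"c.{cv.position}{cv.ref_nt}>{cv.alt_nt}"


# --------------------------------------------------------------------------
# Synonym generation
# --------------------------------------------------------------------------

def protein_synonyms(
    v: ProteinVariant,
    mode: str = "all",
    cds: Optional[str] = None,
    surface: Optional[str] = None,
) -> SynonymSet:
    """Expand a variant into its surface-form synonyms.

    mode ``none``
        only the input surface form (``surface`` or the one-letter form).
    mode ``basic``
        every protein-level syntactic dialect: HGVS three-letter, HGVS
        one-letter, parenthesized HGVS, bare three-/one-letter, plus the
        arrow colloquialisms.
    mode ``all``
        basic forms plus coding-DNA descriptors (compact and spaced) for each
        single-nucleotide substitution consistent with the change — emitted
        only when a CDS for the gene is supplied.

    The output is deterministic, most-specific HGVS first, deduplicated and
    capped at 50 forms; the input surface form is always a member.
    """
    input_form = surface if surface else str(v)
    if mode == "none":
        return SynonymSet(v, (input_form,), mode)
    if mode not in ("basic", "all"):
        raise ValueError(f"unknown synonym mode: {mode!r}")

    three, one = v.three_letter, str(v)
    forms: list[str] = [
        f"p.{three}",
        f"p.{one}",
        f"p.({three})",
        three,
        one,
    ]
    if mode == "all" and cds is not None:
        # an inconsistent CDS (different isoform, too short) simply yields no
        # transcript-level forms: synonym expansion itself never fails
        try:
            cdna = cdna_synonyms(v, cds)
        except (CodonMismatchError, IndexError):
            cdna = []
        forms.extend(render_cdna(cv) for cv in cdna)
        forms.extend(render_cdna(cv, spaced=True) for cv in cdna)
    # extra templated dialects seen in free text
    forms.append(f"{AA_1TO3[v.ref_aa]}{v.position}→{AA_1TO3[v.alt_aa]}")
    forms.append(f"{v.position} {v.ref_aa}→{v.alt_aa}")

    if input_form not in forms:
        forms.insert(0, input_form)
    deduped: list[str] = []
    for f in forms:
        if f not in deduped:
            deduped.append(f)
    return SynonymSet(v, tuple(deduped[:MAX_SYNONYMS]), mode)


def read_cds_fasta(path: str) -> dict[str, str]:
    """Read coding sequences from FASTA; the first header token is the gene symbol."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        gene = rec.id.split()[0].split("|")[0]
        out[gene] = str(rec.seq).upper()
    return out
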
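"""Strand-level data model for overhang-addressed storage DNA.

The storage unit is an *ss-dsDNA*: a mostly double-stranded template whose
3'-terminal region is left single stranded by a single-primer fill-in
reaction.  That exposed 3' overhang is the file address.  Immediately 5' of
the address sits a 23 nt region shared by every strand; it contains the
T7 promoter and doubles as the binding site of the common fill-in primer.

All sequences are plain Python strings written 5'->3' over {A, C, G, T}.
Coordinates are 0-based, half-open, counted from the template's 5' end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
# Design contexts (variant pools) may carry N placeholders.
DESIGN_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: The common fill-in primer; its complement occurs once on every template,
#: inside the shared promoter region.
COMMON_PRIMER = "TCTGCTCTGCACTCGTAATAC"

#: 23 nt shared region on the template (5'->3'), immediately 5' of the
#: address.  The reverse complement of COMMON_PRIMER is inset within it.
PROMOTER_REGION = "C" + str(Seq(COMMON_PRIMER).reverse_complement()) + "G"
assert len(PROMOTER_REGION) == 23


class SequenceError(ValueError):
    """Raised for malformed DNA sequences."""


def validate_sequence(seq: str, *, allow_n: bool = False) -> str:
    """Check alphabet and non-emptiness; return ``seq`` unchanged.

    Raises :class:`SequenceError` naming the first offending position.
    """
    if not seq:
        raise SequenceError("empty sequence")
    alphabet = DESIGN_ALPHABET if allow_n else DNA_ALPHABET
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(f"invalid character {ch!r} at position {i}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (5'->3' in, 5'->3' out)."""
    validate_sequence(seq, allow_n=True)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq))


# ---------------------------------------------------------------------------
# Template layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateLayout:
    """Fixed geometry of a storage template (5'->3').

    ``[payload][promoter region][address]`` with the address at the 3'
    terminus.  Defaults follow the 160 nt design: a 20 nt address inset
    by a 23 nt promoter region.
    """

    total_length: int = 160
    address_length: int = 20
    promoter_region_length: int = 23

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        if self.address_length < 0 or self.promoter_region_length < 0:
            raise ValueError("region lengths must be non-negative")
        if self.payload_length < 0:
            raise ValueError(
                "address + promoter region exceed total template length"
            )

    @property
    def payload_length(self) -> int:
        return (
            self.total_length
            - self.address_length
            - self.promoter_region_length
        )

    @property
    def payload_interval(self) -> tuple[int, int]:
        return (0, self.payload_length)

    @property
    def promoter_interval(self) -> tuple[int, int]:
        return (self.payload_length, self.payload_length + self.promoter_region_length)

    @property
    def address_interval(self) -> tuple[int, int]:
        return (self.total_length - self.address_length, self.total_length)


def make_template(
    payload: str,
    address: str,
    layout: TemplateLayout | None = None,
    promoter_region: str = PROMOTER_REGION,
) -> str:
    """Assemble ``payload + promoter_region + address`` under ``layout``."""
    if layout is None:
        layout = TemplateLayout(
            total_length=len(payload) + len(promoter_region) + len(address),
            address_length=len(address),
            promoter_region_length=len(promoter_region),
        )
    if len(payload) != layout.payload_length:
        raise ValueError(
            f"payload length {len(payload)} != layout payload {layout.payload_length}"
        )
    if len(address) != layout.address_length:
        raise ValueError("address length does not match layout")
    if len(promoter_region) != layout.promoter_region_length:
        raise ValueError("promoter region length does not match layout")
    return payload + promoter_region + address


# ---------------------------------------------------------------------------
# ss-dsDNA strand
# ---------------------------------------------------------------------------

class StrandState(Enum):
    EXPOSED = "exposed"
    LOCKED = "locked"
    RENAMED = "renamed"
    BLOCKED = "blocked"
    BEAD_BOUND = "bead_bound"


@dataclass(frozen=True)
class Attachment:
    """An auxiliary oligo annealed over (part of) the overhang.

    ``pairing_interval`` is in template coordinates.  ``presented`` is the
    oligo's own unpaired segment (5'->3'): the toehold of a lock, or the
    new address displayed by a rename oligo; empty for a full block.
    """

    role: str  # "lock" | "rename" | "block"
    oligo: str
    pairing_interval: tuple[int, int]
    presented: str = ""
    leak_fraction: float = 0.0  # residual accessibility of a low-temp lock


@dataclass
class SSDSDNAStrand:
    """A template plus the duplex interval covered by the filled-in strand."""

    template: str
    layout: TemplateLayout
    duplex_interval: tuple[int, int]
    state: StrandState = StrandState.EXPOSED
    attachments: list[Attachment] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_sequence(self.template)
        if len(self.template) != self.layout.total_length:
            raise ValueError("template length does not match layout")
        lo, hi = self.duplex_interval
        if lo != 0 or hi > len(self.template):
            raise ValueError("duplex must start at the 5' end of the template")

    @property
    def address(self) -> str:
        """The designed 3'-terminal address (regardless of state)."""
        a, b = self.layout.address_interval
        return self.template[a:b]

    @property
    def overhang_interval(self) -> tuple[int, int]:
        return (self.duplex_interval[1], len(self.template))


class PrimerSiteError(ValueError):
    """Raised when the fill-in primer site is absent or ambiguous."""


def build_ssdsdna(
    template: str,
    primer: str = COMMON_PRIMER,
    layout: TemplateLayout | None = None,
) -> SSDSDNAStrand:
    """Model single-primer fill-in: anneal ``primer`` to its unique site and
    extend to a blunt duplex covering everything 5' of the address.

    The template's 3'-terminal ``address_length`` bases remain single
    stranded -- the overhang/address.
    """
    validate_sequence(template)
    validate_sequence(primer)
    if layout is None:
        layout = TemplateLayout(total_length=len(template))
    if len(template) != layout.total_length:
        raise ValueError("template length does not match layout")

    site = reverse_complement(primer)
    n = template.count(site)
    if n == 0:
        raise PrimerSiteError("no primer site on template")
    if n > 1:
        raise PrimerSiteError("ambiguous primer site: multiple matches")
    pos = template.index(site)
    p_lo, p_hi = layout.promoter_interval
    if not (p_lo <= pos and pos + len(site) <= p_hi):
        raise PrimerSiteError("primer site lies outside the promoter region")

    duplex_end = layout.total_length - layout.address_length
    return SSDSDNAStrand(
        template=template,
        layout=layout,
        duplex_interval=(0, duplex_end),
        state=StrandState.EXPOSED,
    )


def overhang_of(strand: SSDSDNAStrand) -> str:
    """Exposed single-stranded 3' region after masking attachments.

    LOCKED and BLOCKED strands expose nothing of their own template; a
    lock's toehold is its *own* unpaired segment, see :func:`lock_toehold`.
    A RENAMED strand's template overhang is paired, the effective address
    being presented by the rename oligo (:func:`effective_address`).
    """
    if strand.state in (StrandState.LOCKED, StrandState.BLOCKED, StrandState.RENAMED):
        return ""
    lo, hi = strand.overhang_interval
    covered = [False] * (hi - lo)
    for att in strand.attachments:
        a, b = att.pairing_interval
        for i in range(max(a, lo), min(b, hi)):
            covered[i - lo] = True
    return "".join(
        ch for ch, c in zip(strand.template[lo:hi], covered) if not c
    )


def lock_toehold(strand: SSDSDNAStrand) -> str:
    """The unpaired segment of an attached lock oligo ('' if not locked)."""
    for att in strand.attachments:
        if att.role == "lock":
            return att.presented
    return ""


def effective_address(strand: SSDSDNAStrand) -> str:
    """The address an accessing oligo can currently hybridize to.

    EXPOSED strands display their template address; RENAMED strands display
    the rename oligo's presented segment; LOCKED/BLOCKED/BEAD_BOUND strands
    display nothing.
    """
    if strand.state == StrandState.EXPOSED:
        return overhang_of(strand)
    if strand.state == StrandState.RENAMED:
        for att in strand.attachments:
            if att.role == "rename":
                return att.presented
    return ""


# ---------------------------------------------------------------------------
# File records
# ---------------------------------------------------------------------------

@dataclass
class FileRecord:
    """All strands sharing one address, with integer copy counts."""

    address: str
    strands: dict[str, SSDSDNAStrand] = field(default_factory=dict)
    copies: dict[str, int] = field(default_factory=dict)

    def add(self, strand_id: str, strand: SSDSDNAStrand, n: int) -> None:
        if n < 0:
            raise ValueError("copy count must be non-negative")
        self.strands[strand_id] = strand
        self.copies[strand_id] = self.copies.get(strand_id, 0) + n

    def total_copies(self) -> int:
        return sum(self.copies.values())


# ---------------------------------------------------------------------------
# FASTA I/O (header dialect: ``>id key=value key=value``)
# ---------------------------------------------------------------------------

def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    parts = description.split()
    ident = parts[0]
    meta = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            meta[k] = v
    return ident, meta


def read_fasta(path: str | Path) -> Iterator[tuple[str, dict[str, str], str]]:
    """Yield ``(id, metadata, sequence)`` triples."""
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, meta = _parse_header(rec.description)
        yield ident, meta, str(rec.seq).upper()


def write_fasta(
    path: str | Path,
    records: Iterable[tuple[str, dict[str, str], str]],
) -> None:
    """Write ``(id, metadata, sequence)`` triples with key=value headers."""
    seqrecords = []
    for ident, meta, seq in records:
        desc = " ".join(f"{k}={v}" for k, v in meta.items())
        seqrecords.append(SeqRecord(Seq(seq), id=ident, description=desc))
    SeqIO.write(seqrecords, str(path), "fasta")
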
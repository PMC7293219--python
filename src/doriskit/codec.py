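"""Byte <-> codeword codec plus the density and capacity models.

One codeword of length ``L`` nt stores one byte.  A strand's payload holds
``floor(payload_capacity_nt / L)`` codeword slots, of which the first
``index_codewords`` encode the strand's ordinal position in the file
(big-endian base 256).  Density is therefore

    density(L) = (payload_capacity_nt - index_codewords * L) / L

bytes per strand (160 and 5 by default), and system capacity scales the
per-strand density by the number of usable addresses, the strands stored
per file, and the physical replication factor:

    capacity = strands_per_file * n_addresses * density / replicates
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .sequences import TemplateLayout, PROMOTER_REGION, max_homopolymer_run

_BASES = "ACGT"

DEFAULT_PAYLOAD_CAPACITY_NT = 160
DEFAULT_INDEX_CODEWORDS = 5
DEFAULT_STRANDS_PER_FILE = 10 ** 9
DEFAULT_REPLICATES = 10


class CodecError(ValueError):
    pass


@dataclass(frozen=True)
class CodewordConstraints:
    """Sequence-composition rules applied when building a codeword table."""

    max_homopolymer: int | None = None

    def allows(self, word: str) -> bool:
        if self.max_homopolymer is not None:
            if max_homopolymer_run(word) > self.max_homopolymer:
                return False
        return True


@dataclass(frozen=True)
class CodecSpec:
    """A byte->codeword bijection plus strand-geometry bookkeeping."""

    L: int
    table: tuple[str, ...]  # table[byte_value] -> codeword
    index_codewords: int = DEFAULT_INDEX_CODEWORDS
    payload_capacity_nt: int = DEFAULT_PAYLOAD_CAPACITY_NT
    _inverse: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.table) != 256 or len(set(self.table)) != 256:
            raise CodecError("table must hold 256 distinct codewords")
        if any(len(w) != self.L for w in self.table):
            raise CodecError("all codewords must have length L")
        if self.index_codewords * self.L > self.payload_capacity_nt:
            raise CodecError("index codewords exceed payload capacity")
        object.__setattr__(
            self, "_inverse", {w: b for b, w in enumerate(self.table)}
        )

    @property
    def slots_per_strand(self) -> int:
        return self.payload_capacity_nt // self.L

    @property
    def data_bytes_per_strand(self) -> int:
        return self.slots_per_strand - self.index_codewords

    @property
    def payload_nt(self) -> int:
        """Actual payload region length (whole codeword slots only)."""
        return self.slots_per_strand * self.L

    def decode_word(self, word: str) -> int | None:
        return self._inverse.get(word)


def make_codeword_table(
    L: int,
    constraints: CodewordConstraints | None = None,
    seed: int | None = None,
    *,
    index_codewords: int = DEFAULT_INDEX_CODEWORDS,
    payload_capacity_nt: int = DEFAULT_PAYLOAD_CAPACITY_NT,
) -> CodecSpec:
    """Deterministic table: the first 256 codewords in lexicographic order
    that satisfy ``constraints``.  For L=4 without constraints this is every
    4-mer.  ``seed`` is reserved for randomized table strategies and is
    ignored by the lexicographic builder.
    """
    if 4 ** L < 256:
        raise CodecError(f"codeword space exhausted: 4^{L} < 256")
    constraints = constraints or CodewordConstraints()
    words: list[str] = []
    for tup in product(_BASES, repeat=L):
        word = "".join(tup)
        if constraints.allows(word):
            words.append(word)
            if len(words) == 256:
                break
    if len(words) < 256:
        raise CodecError("codeword space exhausted: constraints leave < 256 codewords")
    return CodecSpec(
        L=L,
        table=tuple(words),
        index_codewords=index_codewords,
        payload_capacity_nt=payload_capacity_nt,
    )


def density(
    L: int,
    *,
    payload_capacity_nt: int = DEFAULT_PAYLOAD_CAPACITY_NT,
    index_codewords: int = DEFAULT_INDEX_CODEWORDS,
) -> float:
    """Bytes of data per strand at codeword length ``L``."""
    return (payload_capacity_nt - index_codewords * L) / L


def capacity(
    n_addresses: int,
    density_bytes: float,
    *,
    strands_per_file: int = DEFAULT_STRANDS_PER_FILE,
    replicates: int = DEFAULT_REPLICATES,
) -> float:
    """Total system capacity in bytes for ``n_addresses`` usable addresses."""
    if n_addresses < 0:
        raise ValueError("n_addresses must be non-negative")
    return strands_per_file * n_addresses * density_bytes / replicates


def strand_layout_for(codec: CodecSpec, address_length: int = 20) -> TemplateLayout:
    """Layout of an encoded strand: payload slots + promoter region + address."""
    return TemplateLayout(
        total_length=codec.payload_nt + len(PROMOTER_REGION) + address_length,
        address_length=address_length,
        promoter_region_length=len(PROMOTER_REGION),
    )


def encode(
    payload: bytes,
    codec: CodecSpec,
    address: str,
    promoter_region: str = PROMOTER_REGION,
) -> tuple[list[str], dict]:
    """Chunk ``payload`` into strands ``[index][data codewords][promoter][address]``.

    Returns ``(templates, manifest)``; the manifest records the codec
    parameters and the true payload length so that zero-byte padding in the
    final strand can be stripped on decode.
    """
    per = codec.data_bytes_per_strand
    if per <= 0:
        raise CodecError("codec leaves no room for data codewords")
    n_strands = -(-len(payload) // per) if payload else 0
    if n_strands > 256 ** codec.index_codewords:
        raise CodecError("index overflow: payload exceeds index addressing range")

    templates: list[str] = []
    for i in range(n_strands):
        chunk = payload[i * per : (i + 1) * per]
        chunk = chunk + b"\x00" * (per - len(chunk))
        index_bytes = i.to_bytes(codec.index_codewords, "big")
        words = [codec.table[b] for b in index_bytes + chunk]
        templates.append("".join(words) + promoter_region + address)

    manifest = {
        "codeword_length": codec.L,
        "index_codewords": codec.index_codewords,
        "payload_capacity_nt": codec.payload_capacity_nt,
        "payload_length": len(payload),
        "n_strands": n_strands,
        "address": address,
    }
    return templates, manifest


class DecodeError(ValueError):
    pass


def decode(
    strands: list[str],
    codec: CodecSpec,
    payload_length: int | None = None,
) -> bytes:
    """Invert :func:`encode`: sort strands by decoded index and concatenate.

    Without ``payload_length`` (normally taken from the manifest), trailing
    zero bytes of the final strand are stripped -- ambiguous for payloads
    that genuinely end in zero bytes, hence the manifest.
    """
    per = codec.data_bytes_per_strand
    indexed: list[tuple[int, bytes]] = []
    for strand in strands:
        payload_region = strand[: codec.payload_nt]
        values = []
        for slot in range(codec.slots_per_strand):
            word = payload_region[slot * codec.L : (slot + 1) * codec.L]
            v = codec.decode_word(word)
            if v is None:
                raise DecodeError(
                    f"uncorrectable codeword {word!r} in strand "
                    f"{strand[:16]}... at slot {slot}"
                )
            values.append(v)
        idx = int.from_bytes(bytes(values[: codec.index_codewords]), "big")
        indexed.append((idx, bytes(values[codec.index_codewords :])))

    indexed.sort(key=lambda t: t[0])
    data = b"".join(chunk for _, chunk in indexed)
    if payload_length is not None:
        if payload_length > len(data):
            raise DecodeError("manifest payload length exceeds decoded data")
        return data[:payload_length]
    return data.rstrip(b"\x00") if data else data
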
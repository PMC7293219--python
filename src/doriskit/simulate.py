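"""Stochastic in-silico simulator of the overhang-addressed storage lifecycle.

A :class:`Database` maps 20 nt addresses to files (multisets of ss-dsDNA
strands with integer copy counts).  One access cycle is

    separate  -- bead capture of strands whose exposed overhang matches the
                 access oligo (binomial per strand copy),
    ivt       -- T7 transcription of the bead-immobilized file into RNA,
                 with heat/handling losses of the bound file,
    return    -- elution of the surviving bound strands back into the
                 database.

The overhang also carries toehold-mediated file operations: ``lock`` (a
50 nt oligo pairing 20 nt over the address, leaving a 30 nt toehold),
``unlock`` (a key fully complementary to the lock displaces it via that
toehold), ``rename`` (a 40 nt oligo pairing over the old address while
presenting a new one), and ``delete`` (a 20 nt oligo blocking the address
outright).

All randomness is binomial/Poisson sampling on integer copy counts from a
caller-supplied :class:`numpy.random.Generator`, so copy counts are
conserved exactly across a separate/return round trip when no loss step
intervenes.
"""

from __future__ import annotations

import copy as _copy
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sequences import (
    Attachment,
    FileRecord,
    SSDSDNAStrand,
    StrandState,
    effective_address,
    reverse_complement,
)

# Calibrated defaults.  Roughly half of an accessed file is captured per
# separation, and ~50% of it survives five full access cycles, i.e. a
# per-cycle retention of 0.5**(1/5) ~= 0.87.  The captured-strand survival
# implied by those two numbers, 1 - (1-0.87)/0.5 = 0.74, is spread over the
# default 8 h transcription as a per-hour loss rate.
DEFAULT_SEPARATION_PROBABILITY = 0.5
DEFAULT_PER_ACCESS_RETENTION = 0.87
DEFAULT_IVT_HOURS = 8.0
DEFAULT_CAPTURED_SURVIVAL = 1.0 - (1.0 - DEFAULT_PER_ACCESS_RETENTION) / DEFAULT_SEPARATION_PROBABILITY
DEFAULT_IVT_LOSS_RATE = 1.0 - DEFAULT_CAPTURED_SURVIVAL ** (1.0 / DEFAULT_IVT_HOURS)

LOCK_LENGTH = 50
RENAME_LENGTH = 40
ADDRESS_LENGTH = 20


@dataclass(frozen=True)
class AccessParams:
    """Tunable probabilities and conditions of one access cycle."""

    separation_probability: float = DEFAULT_SEPARATION_PROBABILITY
    per_access_retention: float = DEFAULT_PER_ACCESS_RETENTION
    ivt_hours: float = DEFAULT_IVT_HOURS
    ivt_loss_rate: float = DEFAULT_IVT_LOSS_RATE
    elution_efficiency: float = 1.0
    transcription_rate_per_hour: float = 5.0
    temperature_celsius: float = 25.0
    lock_melt_celsius: float = 45.0
    lock_leak_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "separation_probability",
            "per_access_retention",
            "ivt_loss_rate",
            "elution_efficiency",
            "lock_leak_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ivt_hours < 0:
            raise ValueError("ivt_hours must be non-negative")
        if self.temperature_celsius < -273.15:
            raise ValueError("temperature below absolute zero")


@dataclass
class Database:
    files: dict[str, FileRecord] = field(default_factory=dict)
    rng_seed: int = 0
    log: list[dict] = field(default_factory=list)

    def copy(self) -> "Database":
        return Database(
            files=_copy.deepcopy(self.files),
            rng_seed=self.rng_seed,
            log=list(self.log),
        )

    def total_copies(self) -> dict[str, int]:
        return {addr: f.total_copies() for addr, f in self.files.items()}

    def strand_file_map(self) -> dict[str, str]:
        return {
            sid: addr
            for addr, f in self.files.items()
            for sid in f.strands
        }


@dataclass(frozen=True)
class TruncatedProduct:
    """An off-target priming event in PCR-style access (record only)."""

    strand_id: str
    site_start: int  # template coordinate of the off-target site
    orientation: str  # "template" | "complement"


@dataclass(frozen=True)
class TranscriptRecord:
    strand_id: str
    sequence: str  # RNA, 5'->3'
    count: int


# ---------------------------------------------------------------------------
# Access cycle
# ---------------------------------------------------------------------------

def _capture_probability(
    strand: SSDSDNAStrand, oligo: str, params: AccessParams
) -> float:
    """Per-copy capture probability for a bead-linked access oligo."""
    target = reverse_complement(oligo)
    p = params.separation_probability
    if strand.state == StrandState.LOCKED:
        if params.temperature_celsius > params.lock_melt_celsius:
            # lock melted off: the designed address is exposed again
            return p if strand.address == target else 0.0
        leak = max(
            (a.leak_fraction for a in strand.attachments if a.role == "lock"),
            default=0.0,
        )
        return p * leak if strand.address == target else 0.0
    if strand.state == StrandState.BLOCKED:
        return 0.0
    eff = effective_address(strand)
    return p if eff == target else 0.0


def separate(
    db: Database,
    oligo: str,
    params: AccessParams,
    mode: str = "DORIS",
    rng: np.random.Generator | None = None,
) -> tuple[Database, FileRecord]:
    """Bead separation with ``oligo``; returns (retained database, bound file).

    DORIS mode captures only strands whose *exposed* overhang is the exact
    reverse complement of the oligo.  PCR mode models melt-and-prime
    access: the duplex no longer protects internal sites, so off-target
    priming within payloads is recorded as :class:`TruncatedProduct`
    events in the retained database's log.
    """
    mode = mode.upper()
    if mode not in ("DORIS", "PCR"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(db.rng_seed)
    retained = db.copy()
    bound = FileRecord(address=reverse_complement(oligo))
    site = reverse_complement(oligo)

    for addr, frec in retained.files.items():
        for sid, strand in frec.strands.items():
            n = frec.copies.get(sid, 0)
            if n == 0:
                continue
            if mode == "DORIS":
                p = _capture_probability(strand, oligo, params)
            else:
                # melted: priming at the designed address yields full product
                p = (
                    params.separation_probability
                    if strand.address == site
                    else 0.0
                )
                internal = strand.template[: -len(site)]
                start = internal.find(site)
                while start != -1:
                    retained.log.append(
                        {
                            "event": "truncated_product",
                            "record": TruncatedProduct(sid, start, "template"),
                        }
                    )
                    start = internal.find(site, start + 1)
                rc = reverse_complement(strand.template)
                start = rc[len(site):].find(site)
                while start != -1:
                    retained.log.append(
                        {
                            "event": "truncated_product",
                            "record": TruncatedProduct(
                                sid,
                                len(strand.template) - (start + len(site)) - len(site),
                                "complement",
                            ),
                        }
                    )
                    start = rc[len(site):].find(site, start + 1)
            if p <= 0.0:
                continue
            k = int(rng.binomial(n, p))
            if k:
                frec.copies[sid] = n - k
                bound_strand = replace(strand, state=StrandState.BEAD_BOUND)
                bound.add(sid, bound_strand, k)
    retained.log.append(
        {
            "event": "separate",
            "mode": mode,
            "oligo": oligo,
            "captured": bound.total_copies(),
        }
    )
    return retained, bound


def ivt(
    bound_file: FileRecord,
    params: AccessParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptRecord], FileRecord]:
    """T7 in vitro transcription on the bead-immobilized file.

    Transcript numbers are Poisson with mean copies * hours * rate; the
    bound file decays as (1 - ivt_loss_rate)**hours (binomial per strand).
    The transcript is the RNA complement of the template payload region.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    transcripts: list[TranscriptRecord] = []
    surviving = FileRecord(address=bound_file.address)
    survival = (1.0 - params.ivt_loss_rate) ** params.ivt_hours
    for sid, strand in bound_file.strands.items():
        n = bound_file.copies.get(sid, 0)
        if n == 0:
            continue
        mean = n * params.ivt_hours * params.transcription_rate_per_hour
        count = int(rng.poisson(mean)) if mean > 0 else 0
        if count:
            lo, hi = strand.layout.payload_interval
            rna = reverse_complement(strand.template[lo:hi]).replace("T", "U")
            transcripts.append(TranscriptRecord(sid, rna, count))
        k = int(rng.binomial(n, survival))
        if k:
            surviving.add(sid, strand, k)
    return transcripts, surviving


def return_file(
    db: Database,
    file: FileRecord,
    params: AccessParams,
    rng: np.random.Generator | None = None,
) -> Database:
    """Elute the bound file back into the database (binomial per strand)."""
    if rng is None:
        rng = np.random.default_rng(db.rng_seed)
    out = db.copy()
    for sid, strand in file.strands.items():
        n = file.copies.get(sid, 0)
        k = int(rng.binomial(n, params.elution_efficiency)) if n else 0
        if k == 0:
            continue
        target = out.files.setdefault(
            strand.address, FileRecord(address=strand.address)
        )
        returned = replace(strand, state=StrandState.EXPOSED)
        target.add(sid, returned, k)
    out.log.append({"event": "return_file", "address": file.address})
    return out


def repeat_access(
    db: Database,
    address: str,
    n: int,
    params: AccessParams,
    rng: np.random.Generator | None = None,
) -> tuple[Database, pd.DataFrame]:
    """Run ``n`` full access cycles against ``address``.

    Returns the final database and a per-cycle retention table (% of each
    file's initial copies still in the database; row 0 is the initial
    state).  Files that are never accessed stay near 100% by construction.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if rng is None:
        rng = np.random.default_rng(db.rng_seed)
    initial = db.total_copies()
    oligo = reverse_complement(address)
    rows = [{"cycle": 0, **{a: 100.0 for a in initial}}]
    current = db
    for cycle in range(1, n + 1):
        current, bound = separate(current, oligo, params, "DORIS", rng)
        _, surviving = ivt(bound, params, rng)
        current = return_file(current, surviving, params, rng)
        counts = current.total_copies()
        rows.append(
            {
                "cycle": cycle,
                **{
                    a: (100.0 * counts.get(a, 0) / initial[a])
                    if initial[a]
                    else math.nan
                    for a in initial
                },
            }
        )
    return current, pd.DataFrame(rows).set_index("cycle")


def min_initial_copies(
    n_accesses: int,
    per_access_retention: float = DEFAULT_PER_ACCESS_RETENTION,
    rel_tol: float = 0.01,
) -> int:
    """Smallest initial copy count whose expected survivorship after
    ``n_accesses`` cycles is still at least one copy (within ``rel_tol``)."""
    if n_accesses < 0:
        raise ValueError("n_accesses must be non-negative")
    surviving_fraction = per_access_retention ** n_accesses
    if surviving_fraction <= 0:
        raise ValueError("retention of zero never preserves a copy")
    return math.ceil((1.0 - rel_tol) / surviving_fraction)


# ---------------------------------------------------------------------------
# Toehold file operations
# ---------------------------------------------------------------------------

class FileOperationError(ValueError):
    pass


def make_lock(address: str, toehold: str | None = None, seed: int = 0) -> str:
    """A 50 nt lock: a random (seeded) 30 nt toehold followed by the 20 nt
    complement of ``address``."""
    if toehold is None:
        rng = np.random.default_rng(seed)
        toehold = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
    return toehold + reverse_complement(address)


def make_rename_oligo(old_address: str, new_address: str) -> str:
    """A 40 nt rename oligo: the new address presented 5' of the 20 nt
    complement of the old address."""
    return new_address + reverse_complement(old_address)


def _all_exposed(file: FileRecord) -> None:
    for sid, strand in file.strands.items():
        if strand.state != StrandState.EXPOSED:
            raise FileOperationError(
                f"strand {sid} has no exposed overhang (state {strand.state.value})"
            )


def lock(
    file: FileRecord,
    lock_strand: str,
    add_temperature_celsius: float,
    *,
    leak_fraction: float = 0.05,
    full_lock_celsius: float = 45.0,
) -> FileRecord:
    """Anneal a lock over the file's address.

    The lock must contain the exact 20 nt complement of the address; the
    remainder is its single-stranded toehold.  Locking below
    ``full_lock_celsius`` is leaky: a ``leak_fraction`` per-copy chance of
    spurious capture is recorded on the attachment.
    """
    comp = reverse_complement(file.address)
    if comp not in lock_strand:
        raise FileOperationError("lock lacks a complementary region to the address")
    _all_exposed(file)
    i = lock_strand.index(comp)
    toehold = lock_strand[:i] + lock_strand[i + len(comp):]
    leak = 0.0 if add_temperature_celsius >= full_lock_celsius else leak_fraction
    out = FileRecord(address=file.address)
    for sid, strand in file.strands.items():
        att = Attachment(
            role="lock",
            oligo=lock_strand,
            pairing_interval=strand.layout.address_interval,
            presented=toehold,
            leak_fraction=leak,
        )
        locked = replace(
            strand,
            state=StrandState.LOCKED,
            attachments=strand.attachments + [att],
        )
        out.add(sid, locked, file.copies.get(sid, 0))
    return out


def unlock(
    file: FileRecord,
    key: str,
    temperature_celsius: float = 25.0,
) -> FileRecord:
    """Toehold-mediated displacement of the lock by its full complement.

    Works at any temperature >= 25 C thanks to the 30 nt toehold.  A
    mismatched key leaves the file locked (with a warning).
    """
    out = FileRecord(address=file.address)
    displaced = False
    for sid, strand in file.strands.items():
        locks = [a for a in strand.attachments if a.role == "lock"]
        if strand.state == StrandState.LOCKED and locks:
            if key == reverse_complement(locks[0].oligo):
                rest = [a for a in strand.attachments if a.role != "lock"]
                strand = replace(
                    strand, state=StrandState.EXPOSED, attachments=rest
                )
                displaced = True
        out.add(sid, strand, file.copies.get(sid, 0))
    if not displaced and file.strands:
        warnings.warn("key does not match the lock; file remains locked")
    return out


def rename(file: FileRecord, rename_oligo: str) -> FileRecord:
    """Re-address the file: a 40 nt oligo pairs over the old address and
    presents a new 20 nt address in its place."""
    if len(rename_oligo) != RENAME_LENGTH:
        raise FileOperationError(
            f"rename oligo must be {RENAME_LENGTH} nt, got {len(rename_oligo)}"
        )
    comp = reverse_complement(file.address)
    if rename_oligo.endswith(comp):
        presented = rename_oligo[: -len(comp)]
    elif rename_oligo.startswith(comp):
        presented = rename_oligo[len(comp):]
    else:
        raise FileOperationError("rename oligo lacks the old-address complement")
    _all_exposed(file)
    out = FileRecord(address=presented)
    for sid, strand in file.strands.items():
        att = Attachment(
            role="rename",
            oligo=rename_oligo,
            pairing_interval=strand.layout.address_interval,
            presented=presented,
        )
        renamed = replace(
            strand,
            state=StrandState.RENAMED,
            attachments=strand.attachments + [att],
        )
        out.add(sid, renamed, file.copies.get(sid, 0))
    return out


def delete(file: FileRecord, block_oligo: str) -> FileRecord:
    """Block the file's effective address with its exact 20 nt complement;
    no oligo can capture the strands thereafter."""
    if not file.strands:
        if block_oligo != reverse_complement(file.address):
            raise FileOperationError("block oligo does not match the file address")
        return FileRecord(address=file.address)
    out = FileRecord(address=file.address)
    for sid, strand in file.strands.items():
        eff = effective_address(strand)
        if not eff:
            raise FileOperationError(
                f"strand {sid} exposes no address to block (state {strand.state.value})"
            )
        if block_oligo != reverse_complement(eff):
            raise FileOperationError("block oligo does not match the exposed address")
        att = Attachment(
            role="block",
            oligo=block_oligo,
            pairing_interval=strand.layout.address_interval,
            presented="",
        )
        blocked = replace(
            strand,
            state=StrandState.BLOCKED,
            attachments=strand.attachments + [att],
        )
        out.add(sid, blocked, file.copies.get(sid, 0))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Per-file and per-strand bookkeeping of one access.

    Percentages; ``None`` marks an undefined metric (zero denominator).
    """

    file_specificity: dict[str, float | None]
    separation_efficiency: dict[str, float | None]
    retention_rate: dict[str, float | None]
    normalized_abundance: dict[str, float | None]


def compute_metrics(
    before: Database,
    sample: FileRecord,
    after: Database,
) -> MetricsReport:
    """Specificity and efficiency of ``sample`` plus database retention.

    * specificity(F) = copies of file F in the sample / total sample copies
    * separation efficiency(F) = file-F sample copies / file-F copies before
    * retention(F) = file-F copies after / before
    * normalized abundance(s) = strand-s copies after / before
    """
    strand_file = before.strand_file_map()
    before_counts = before.total_copies()
    after_counts = after.total_copies()

    sample_by_file: dict[str, int] = {addr: 0 for addr in before.files}
    for sid, n in sample.copies.items():
        f = strand_file.get(sid)
        if f is not None:
            sample_by_file[f] = sample_by_file.get(f, 0) + n
    total_sample = sample.total_copies()

    specificity = {
        addr: (100.0 * n / total_sample) if total_sample else None
        for addr, n in sample_by_file.items()
    }
    efficiency = {
        addr: (100.0 * sample_by_file.get(addr, 0) / before_counts[addr])
        if before_counts.get(addr)
        else None
        for addr in before.files
    }
    retention = {
        addr: (100.0 * after_counts.get(addr, 0) / before_counts[addr])
        if before_counts.get(addr)
        else None
        for addr in before.files
    }

    norm_abundance: dict[str, float | None] = {}
    before_strands = {
        sid: frec.copies.get(sid, 0)
        for frec in before.files.values()
        for sid in frec.strands
    }
    after_strands: dict[str, int] = {}
    for frec in after.files.values():
        for sid in frec.strands:
            after_strands[sid] = after_strands.get(sid, 0) + frec.copies.get(sid, 0)
    for sid, n0 in before_strands.items():
        norm_abundance[sid] = (after_strands.get(sid, 0) / n0) if n0 else None

    return MetricsReport(
        file_specificity=specificity,
        separation_efficiency=efficiency,
        retention_rate=retention,
        normalized_abundance=norm_abundance,
    )
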
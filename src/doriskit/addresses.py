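"""Orthogonal overhang-address design and the payload-conflict survey.

Addresses are 20 nt single-stranded overhangs.  Two regimes are modelled:

* **PCR access** -- primers see melted, fully single-stranded DNA, so a
  usable address must stay Hamming-far (>= threshold, default 6) both from
  every other accepted address *and* from every 20 nt window of every data
  payload (either strand).
* **Overhang (DORIS) access** -- the payload stays double stranded, so
  only mutual orthogonality between addresses is required; payload content
  is irrelevant to the address budget.

The survey quantifies the consequence: as codewords shrink (denser
encodings), payload sequence diversity rises and the PCR-usable address
count collapses, while the overhang-access count is unchanged.

Hot loops pack 20-mers into one ``uint64`` (2 bits/base) and count
mismatching base positions via XOR + popcount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codec as codec_mod
from .sequences import (
    gc_fraction,
    max_homopolymer_run,
    reverse_complement,
    validate_sequence,
)

ADDRESS_LENGTH = 20
DEFAULT_THRESHOLD = 6

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

_MASK01 = np.uint64(0x5555555555555555)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AddressCandidate:
    sequence: str
    gc_fraction: float
    max_homopolymer: int

    @classmethod
    def from_sequence(cls, seq: str) -> "AddressCandidate":
        validate_sequence(seq)
        return cls(seq, gc_fraction(seq), max_homopolymer_run(seq))


# ---------------------------------------------------------------------------
# Bit packing helpers
# ---------------------------------------------------------------------------

def _encode_bases(seqs: list[str]) -> np.ndarray:
    """(n, len) uint8 array of 2-bit base codes."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    m = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[buf].reshape(len(seqs), m)
    if (codes == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return codes


def pack_kmers(seqs: list[str]) -> np.ndarray:
    """Pack equal-length (<=32 nt) sequences into uint64s, 2 bits per base."""
    codes = _encode_bases(seqs)
    if codes.shape[1] > 32:
        raise ValueError("pack_kmers supports length <= 32")
    weights = (np.uint64(1) << (2 * np.arange(codes.shape[1], dtype=np.uint64)))
    return codes.astype(np.uint64) @ weights


def packed_hamming(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Base-wise Hamming distance between broadcastable packed arrays."""
    x = a ^ b
    mism = (x | (x >> np.uint64(1))) & _MASK01
    return np.bitwise_count(mism)


def strand_windows_packed(strands: list[str], k: int = ADDRESS_LENGTH) -> np.ndarray:
    """All k-mer windows of every strand, packed; forward orientation only.

    Comparing both orientations of a *query* against these forward windows
    is equivalent to comparing the query against windows of both strand
    orientations (reverse-complementing both sides preserves distance).
    Strands may have different lengths.  Duplicate windows are collapsed.
    """
    out: list[np.ndarray] = []
    weights = (np.uint64(1) << (2 * np.arange(k, dtype=np.uint64)))
    by_len: dict[int, list[str]] = {}
    for s in strands:
        by_len.setdefault(len(s), []).append(s)
    for m, group in by_len.items():
        if m < k:
            continue
        codes = _encode_bases(group)
        win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
        packed = win.astype(np.uint64) @ weights
        out.append(packed.ravel())
    if not out:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(out))


# ---------------------------------------------------------------------------
# Candidate generation and screening
# ---------------------------------------------------------------------------

def generate_candidates(
    n: int,
    seed: int,
    *,
    length: int = ADDRESS_LENGTH,
    gc_range: tuple[float, float] = (0.40, 0.60),
    max_homopolymer: int = 3,
) -> list[AddressCandidate]:
    """Seeded uniform random candidates filtered by standard primer
    heuristics (GC fraction window, homopolymer cap)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[AddressCandidate] = []
    lo, hi = gc_range
    while len(out) < n:
        batch = rng.integers(0, 4, size=(max(1024, n), length))
        for row in batch:
            seq = "".join(bases[row])
            gc = gc_fraction(seq)
            if not (lo <= gc <= hi):
                continue
            if max_homopolymer_run(seq) > max_homopolymer:
                continue
            out.append(AddressCandidate(seq, gc, max_homopolymer_run(seq)))
            if len(out) == n:
                break
    return out


def mutual_orthogonality_filter(
    candidates: list[AddressCandidate],
    threshold: int = DEFAULT_THRESHOLD,
) -> list[AddressCandidate]:
    """Greedy accept-in-order screen: a candidate survives if it is at
    Hamming distance >= threshold from every previously accepted address
    and from each accepted address's reverse complement."""
    survivors: list[AddressCandidate] = []
    accepted = np.empty(2 * len(candidates), dtype=np.uint64)
    n_acc = 0
    thr = np.uint64(threshold)
    for cand in candidates:
        fwd = pack_kmers([cand.sequence])
        if n_acc:
            d = packed_hamming(accepted[:n_acc], fwd)
            if (d < thr).any():
                continue
        survivors.append(cand)
        accepted[n_acc] = fwd[0]
        accepted[n_acc + 1] = pack_kmers([reverse_complement(cand.sequence)])[0]
        n_acc += 2
    return survivors


def payload_conflict(
    address: str,
    strand: str,
    threshold: int = DEFAULT_THRESHOLD,
) -> bool:
    """True iff the address (or its reverse complement) comes within
    ``threshold`` mismatches of any 20 nt window of the strand (or its
    reverse complement)."""
    if len(strand) < len(address):
        raise ValueError("strand shorter than address")
    wins = strand_windows_packed([strand], k=len(address))
    queries = pack_kmers([address, reverse_complement(address)])
    d = packed_hamming(wins[:, None], queries[None, :])
    return bool((d < np.uint64(threshold)).any())


# ---------------------------------------------------------------------------
# Monte Carlo survey
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyResult:
    mode: str  # "PCR" | "DORIS"
    L: int | None
    candidates_tested: int
    survivors: int
    capacity_bytes: float | None
    seed: int

    def __post_init__(self) -> None:
        if self.survivors > self.candidates_tested:
            raise ValueError("survivors cannot exceed candidates tested")


def _mismatch_deltas(length: int, max_mismatches: int) -> np.ndarray:
    """All packed XOR deltas flipping at most ``max_mismatches`` base
    positions of a 2-bit-packed ``length``-mer (cached per arguments)."""
    key = (length, max_mismatches)
    cached = _DELTA_CACHE.get(key)
    if cached is not None:
        return cached
    from itertools import combinations, product as iproduct

    deltas = [0]
    for k in range(1, max_mismatches + 1):
        for positions in combinations(range(length), k):
            for vals in iproduct((1, 2, 3), repeat=k):
                d = 0
                for pos, v in zip(positions, vals):
                    d |= v << (2 * pos)
                deltas.append(d)
    out = np.array(sorted(set(deltas)), dtype=np.uint64)
    _DELTA_CACHE[key] = out
    return out


_DELTA_CACHE: dict[tuple[int, int], np.ndarray] = {}


class _WindowIndex:
    """Exact near-neighbor search over packed k-mer windows.

    Pigeonhole on two half-words: a window within ``threshold - 1``
    mismatches of a query has at least one half within
    ``(threshold - 1) // 2`` mismatches, so candidate hits are found by
    enumerating half-word neighborhoods and verified by an exact packed
    Hamming distance.  Equivalent to a full scan, run in sublinear time.
    """

    def __init__(self, windows: np.ndarray, k: int, threshold: int) -> None:
        self.windows = windows
        self.k = k
        self.threshold = threshold
        self.k_lo = k // 2
        self.k_hi = k - self.k_lo
        self.radius = (threshold - 1) // 2
        lo_mask = (np.uint64(1) << np.uint64(2 * self.k_lo)) - np.uint64(1)
        self.lo_mask = lo_mask
        halves_lo = windows & lo_mask
        halves_hi = windows >> np.uint64(2 * self.k_lo)
        self.order_lo = np.argsort(halves_lo, kind="stable")
        self.sorted_lo = halves_lo[self.order_lo]
        self.order_hi = np.argsort(halves_hi, kind="stable")
        self.sorted_hi = halves_hi[self.order_hi]
        self.deltas_lo = _mismatch_deltas(self.k_lo, self.radius)
        self.deltas_hi = _mismatch_deltas(self.k_hi, self.radius)

    def _half_hits(self, half: np.uint64, deltas: np.ndarray,
                   sorted_h: np.ndarray, order: np.ndarray) -> np.ndarray:
        neigh = half ^ deltas
        starts = np.searchsorted(sorted_h, neigh, side="left")
        ends = np.searchsorted(sorted_h, neigh, side="right")
        nz = starts < ends
        if not nz.any():
            return np.empty(0, dtype=np.int64)
        chunks = [order[s:e] for s, e in zip(starts[nz], ends[nz])]
        return np.concatenate(chunks)

    def conflicts(self, query: np.uint64) -> bool:
        """True iff some window is within ``threshold - 1`` mismatches."""
        lo = query & self.lo_mask
        hi = query >> np.uint64(2 * self.k_lo)
        idx = self._half_hits(lo, self.deltas_lo, self.sorted_lo, self.order_lo)
        if idx.size:
            d = packed_hamming(self.windows[idx], np.uint64(query))
            if (d < self.threshold).any():
                return True
        idx = self._half_hits(hi, self.deltas_hi, self.sorted_hi, self.order_hi)
        if idx.size:
            d = packed_hamming(self.windows[idx], np.uint64(query))
            if (d < self.threshold).any():
                return True
        return False


def _screen_payload_conflicts(
    candidates: list[AddressCandidate],
    windows: np.ndarray,
    threshold: int,
    k: int = ADDRESS_LENGTH,
) -> list[AddressCandidate]:
    """Drop candidates whose minimum window distance (either orientation)
    falls below ``threshold``; exact, via the half-word neighbor index."""
    if windows.size == 0 or not candidates:
        return list(candidates)
    index = _WindowIndex(windows, k, threshold)
    seqs = [c.sequence for c in candidates]
    fwd = pack_kmers(seqs)
    rev = pack_kmers([reverse_complement(s) for s in seqs])
    return [
        c
        for c, f, r in zip(candidates, fwd, rev)
        if not (index.conflicts(f) or index.conflicts(r))
    ]


def monte_carlo_survey(
    n_candidates: int,
    database: list[str],
    mode: str,
    threshold: int = DEFAULT_THRESHOLD,
    seed: int = 0,
    *,
    codeword_length: int | None = None,
    payload_sample: int | None = 10_000,
    candidates: list[AddressCandidate] | None = None,
    capacity_kwargs: dict | None = None,
) -> SurveyResult:
    """Estimate how many candidate addresses survive screening.

    PCR mode requires both mutual orthogonality and absence of payload
    conflicts over a random sample of database strands; DORIS mode applies
    mutual orthogonality only.  Reproducible given ``seed``.
    """
    mode = mode.upper()
    if mode not in ("PCR", "DORIS"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "PCR" and not database:
        raise ValueError("PCR mode requires a non-empty database")

    if candidates is None:
        candidates = generate_candidates(n_candidates, seed)
    survivors = mutual_orthogonality_filter(candidates, threshold)

    if mode == "PCR":
        rng = np.random.default_rng(seed + 1)
        if payload_sample is not None and payload_sample < len(database):
            idx = rng.choice(len(database), size=payload_sample, replace=False)
            sampled = [database[i] for i in idx]
        else:
            sampled = list(database)
        windows = strand_windows_packed(sampled)
        survivors = _screen_payload_conflicts(survivors, windows, threshold)

    cap = None
    if codeword_length is not None:
        cap = codec_mod.capacity(
            len(survivors),
            codec_mod.density(codeword_length),
            **(capacity_kwargs or {}),
        )
    return SurveyResult(
        mode=mode,
        L=codeword_length,
        candidates_tested=len(candidates),
        survivors=len(survivors),
        capacity_bytes=cap,
        seed=seed,
    )


def make_survey_database(
    L: int,
    n_strands: int,
    seed: int,
    *,
    address: str = "A" * ADDRESS_LENGTH,
) -> list[str]:
    """Synthetic database for the survey: ``n_strands`` templates produced
    by encoding a random payload at codeword length ``L``."""
    spec = codec_mod.make_codeword_table(L)
    per = spec.data_bytes_per_strand
    rng = np.random.default_rng(seed)
    payload = rng.integers(0, 256, size=n_strands * per, dtype=np.uint8).tobytes()
    strands, _ = codec_mod.encode(payload, spec, address)
    return strands


def capacity_curve(
    L_values: list[int],
    mode: str,
    *,
    n_candidates: int,
    n_strands: int,
    threshold: int = DEFAULT_THRESHOLD,
    seed: int = 0,
    payload_sample: int | None = 10_000,
    capacity_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Survey each codeword length and join with density and capacity.

    The candidate set is generated once from ``seed`` and reused for every
    L so that the DORIS survivor count is identical across the curve.
    """
    candidates = generate_candidates(n_candidates, seed)
    rows = []
    for L in L_values:
        database = make_survey_database(L, n_strands, seed + L) if n_strands else []
        res = monte_carlo_survey(
            n_candidates,
            database,
            mode,
            threshold,
            seed,
            codeword_length=L,
            payload_sample=payload_sample,
            candidates=candidates,
            capacity_kwargs=capacity_kwargs,
        )
        rows.append(
            {
                "mode": res.mode,
                "L": L,
                "candidates": res.candidates_tested,
                "survivors": res.survivors,
                "density": codec_mod.density(L),
                "capacity": res.capacity_bytes,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
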
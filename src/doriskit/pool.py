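"""Promoter-variant pool design and sequencing-readout analysis.

The pool is a saturation-mutagenesis library around the T7 promoter on the
160 nt storage template: 1024 strands enumerate every 5-mer immediately
upstream of the promoter (inside the single-stranded overhang) and 64
strands enumerate every 3-mer immediately downstream (inside the
transcribed payload), for 1088 distinct strands.  Because the upstream
variant is not transcribed, every strand carries a short payload barcode
identifying its variant.

A seeded read simulator emulates the IVT -> RT-PCR -> sequencing readout
(multinomial sampling proportional to abundance x per-variant transcription
efficiency, with substitution/indel errors), and the analysis side computes
per-variant normalized abundance (post/pre read ratio), quartile
position-frequency matrices, A/T-content group statistics, and per-position
error rates from edit-distance alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product

import edlib
import numpy as np
import pandas as pd
from scipy import stats as sps

from .addresses import hamming_distance
from .sequences import PROMOTER_REGION, TemplateLayout, reverse_complement

UPSTREAM_5 = "UPSTREAM_5"
DOWNSTREAM_3 = "DOWNSTREAM_3"

_BASES = "ACGT"

DEFAULT_BARCODE_LENGTH = 8


@dataclass(frozen=True)
class PoolRecord:
    index: int
    variant_class: str  # UPSTREAM_5 | DOWNSTREAM_3
    variant: str
    barcode: str
    template: str


@dataclass
class VariantPool:
    layout: TemplateLayout
    promoter: str
    records: list[PoolRecord]
    barcode_interval: tuple[int, int]

    @property
    def strands(self) -> list[str]:
        return [r.template for r in self.records]

    @property
    def variant_table(self) -> dict[str, tuple[str, str]]:
        return {r.barcode: (r.variant, r.variant_class) for r in self.records}

    def variant_positions(self, variant_class: str) -> tuple[int, int]:
        """Template interval holding the variant bases of a class."""
        p_lo, p_hi = self.layout.promoter_interval
        if variant_class == UPSTREAM_5:
            return (p_hi, p_hi + 5)
        if variant_class == DOWNSTREAM_3:
            return (p_lo - 3, p_lo)
        raise ValueError(f"unknown variant class {variant_class!r}")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _make_barcodes(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 2
) -> list[str]:
    """Greedy seeded barcodes with pairwise Hamming distance >= min_distance."""
    if 4 ** length < n:
        raise ValueError("barcode space exhausted")
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError("barcode space exhausted under the distance rule")
        cand = _random_seq(rng, length)
        if all(hamming_distance(cand, b) >= min_distance for b in accepted):
            accepted.append(cand)
    return accepted


def build_variant_pool(
    layout: TemplateLayout | None = None,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
    seed: int = 0,
) -> VariantPool:
    """Enumerate the 1024 upstream 5-mer and 64 downstream 3-mer variants.

    Deterministic given ``seed`` (which fixes the barcodes and the constant
    filler/address context shared by all strands).
    """
    layout = layout or TemplateLayout()
    rng = np.random.default_rng(seed)
    n_up, n_down = 4 ** 5, 4 ** 3
    barcodes = _make_barcodes(n_up + n_down, barcode_length, rng)

    # Constant sequence context shared across the pool.
    address_core = _random_seq(rng, layout.address_length - 5)  # 3' of upstream NNNNN
    full_address = _random_seq(rng, layout.address_length)  # downstream strands
    filler_len = layout.payload_length - barcode_length
    filler = _random_seq(rng, filler_len)

    records: list[PoolRecord] = []
    idx = 0
    for tup in product(_BASES, repeat=5):
        v = "".join(tup)
        bc = barcodes[idx]
        payload = bc + filler
        template = payload + PROMOTER_REGION + v + address_core
        records.append(PoolRecord(idx, UPSTREAM_5, v, bc, template))
        idx += 1
    for tup in product(_BASES, repeat=3):
        v = "".join(tup)
        bc = barcodes[idx]
        payload = bc + filler[:-3] + v
        template = payload + PROMOTER_REGION + full_address
        records.append(PoolRecord(idx, DOWNSTREAM_3, v, bc, template))
        idx += 1

    pool = VariantPool(
        layout=layout,
        promoter=PROMOTER_REGION,
        records=records,
        barcode_interval=(0, barcode_length),
    )
    if len({r.template for r in pool.records}) != len(pool.records):
        raise AssertionError("variant pool strands are not all distinct")
    return pool


# ---------------------------------------------------------------------------
# Synthetic reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorProfile:
    substitution_rate: float = 1e-3
    insertion_rate: float = 2e-4
    deletion_rate: float = 5e-4

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass
class ReadSet:
    reads: list[str]
    provenance: str  # "pre_library" | "post_ivt"
    error_profile: ErrorProfile
    truth: list[int] = field(default_factory=list)  # source record index


def _resolve_efficiencies(pool: VariantPool, efficiency_model) -> np.ndarray:
    n = len(pool.records)
    if efficiency_model is None:
        return np.ones(n)
    if isinstance(efficiency_model, dict):
        eff = np.empty(n)
        for r in pool.records:
            key = (r.variant_class, r.variant)
            eff[r.index] = efficiency_model.get(key, efficiency_model.get(r.variant, 1.0))
        return eff
    eff = np.asarray(efficiency_model, dtype=float)
    if eff.shape != (n,):
        raise ValueError("efficiency array must have one entry per pool record")
    return eff


def _mutate(seq: str, rng: np.random.Generator, profile: ErrorProfile) -> str:
    """Inject per-base substitution / insertion / deletion events."""
    m = len(seq)
    sub = rng.random(m) < profile.substitution_rate
    ins = rng.random(m) < profile.insertion_rate
    dele = rng.random(m) < profile.deletion_rate
    if not (sub.any() or ins.any() or dele.any()):
        return seq
    out: list[str] = []
    for i, ch in enumerate(seq):
        if dele[i]:
            pass
        elif sub[i]:
            out.append(_BASES[(_BASES.index(ch) + rng.integers(1, 4)) % 4])
        else:
            out.append(ch)
        if ins[i]:
            out.append(_BASES[rng.integers(0, 4)])
    return "".join(out)


def simulate_reads(
    pool: VariantPool,
    efficiency_model,
    n_reads: int,
    error_profile: ErrorProfile | None = None,
    seed: int = 0,
    provenance: str = "post_ivt",
) -> ReadSet:
    """Draw reads multinomially, weighted by transcription efficiency for
    ``post_ivt`` provenance and uniformly for ``pre_library``."""
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if provenance not in ("pre_library", "post_ivt"):
        raise ValueError(f"unknown provenance {provenance!r}")
    profile = error_profile or ErrorProfile()
    rng = np.random.default_rng(seed)
    eff = _resolve_efficiencies(pool, efficiency_model)
    if (eff < 0).any():
        raise ValueError("efficiencies must be non-negative")
    weights = eff if provenance == "post_ivt" else np.ones(len(pool.records))
    p = weights / weights.sum()
    counts = rng.multinomial(n_reads, p)

    # Fast path: most reads are error free; mutate lazily per read.
    p_any = 1.0 - (
        (1.0 - profile.substitution_rate)
        * (1.0 - profile.insertion_rate)
        * (1.0 - profile.deletion_rate)
    ) ** len(pool.records[0].template)
    reads: list[str] = []
    truth: list[int] = []
    for rec, k in zip(pool.records, counts):
        if k == 0:
            continue
        n_mut = rng.binomial(k, p_any) if p_any > 0 else 0
        reads.extend([rec.template] * (k - n_mut))
        for _ in range(n_mut):
            mutated = rec.template
            while mutated == rec.template:
                mutated = _mutate(rec.template, rng, profile)
            reads.append(mutated)
        truth.extend([rec.index] * k)
    return ReadSet(reads=reads, provenance=provenance,
                   error_profile=profile, truth=truth)


# ---------------------------------------------------------------------------
# Readout analysis
# ---------------------------------------------------------------------------

def demultiplex(reads: ReadSet, pool: VariantPool) -> tuple[np.ndarray, int]:
    """Assign each read by its barcode locus (<=1 mismatch, ties unassigned).

    Returns ``(counts_per_record, n_unassigned)``.
    """
    lo, hi = pool.barcode_interval
    exact = {r.barcode: r.index for r in pool.records}
    barcodes = [r.barcode for r in pool.records]
    counts = np.zeros(len(pool.records), dtype=np.int64)
    unassigned = 0
    for read in reads.reads:
        bc = read[lo:hi]
        idx = exact.get(bc)
        if idx is not None:
            counts[idx] += 1
            continue
        if len(bc) != hi - lo:
            unassigned += 1
            continue
        dists = [hamming_distance(bc, b) for b in barcodes]
        dmin = min(dists)
        if dmin > 1 or dists.count(dmin) != 1:
            unassigned += 1
        else:
            counts[dists.index(dmin)] += 1
    return counts, unassigned


def normalized_abundance(post_counts, pre_counts) -> np.ndarray:
    """Per-variant post/pre read-count ratio; NaN where pre is zero."""
    post = np.asarray(post_counts, dtype=float)
    pre = np.asarray(pre_counts, dtype=float)
    if post.shape != pre.shape:
        raise ValueError("count arrays must share a variant universe")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pre > 0, post / np.where(pre > 0, pre, 1.0), np.nan)
    return out


def quartile_pfms(
    abundances, pool: VariantPool
) -> list[dict[str, pd.DataFrame]]:
    """Split variants into 4 abundance quartiles (ascending; ties broken by
    variant sequence) and build a per-class position-frequency matrix for
    each quartile.  Undefined (NaN) abundances are excluded.
    """
    ab = np.asarray(abundances, dtype=float)
    if ab.shape != (len(pool.records),):
        raise ValueError("abundances must have one entry per pool record")
    defined = [i for i in range(len(ab)) if not np.isnan(ab[i])]
    if len(defined) < 4:
        raise ValueError("need at least 4 defined abundances")
    order = sorted(defined, key=lambda i: (ab[i], pool.records[i].variant))
    groups = np.array_split(order, 4)

    out: list[dict[str, pd.DataFrame]] = []
    for group in groups:
        by_class: dict[str, pd.DataFrame] = {}
        for cls in (UPSTREAM_5, DOWNSTREAM_3):
            members = [pool.records[i] for i in group
                       if pool.records[i].variant_class == cls]
            if not members:
                continue
            width = len(members[0].variant)
            mat = np.zeros((width, 4))
            for rec in members:
                for j, ch in enumerate(rec.variant):
                    mat[j, _BASES.index(ch)] += 1
            mat /= len(members)
            by_class[cls] = pd.DataFrame(
                mat, columns=list(_BASES),
                index=pd.RangeIndex(width, name="position"),
            )
        out.append(by_class)
    return out


@dataclass
class ATContentResult:
    summary: pd.DataFrame  # group label, n, mean/std abundance
    f_statistic: float | None
    p_value: float | None
    tukey: pd.DataFrame | None
    notice: str | None = None


def at_content_groups(
    abundances, pool: VariantPool
) -> dict[str, ATContentResult]:
    """Bucket variants by A/T fraction of the variant positions and compare
    bucket abundances: one-way ANOVA plus Tukey-Kramer pairwise tests.

    Returns one result per variant class (buckets 0,20,...,100% for 5-mers
    and 0,33,67,100% for 3-mers).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    ab = np.asarray(abundances, dtype=float)
    results: dict[str, ATContentResult] = {}
    for cls in (UPSTREAM_5, DOWNSTREAM_3):
        recs = [r for r in pool.records if r.variant_class == cls]
        if not recs:
            continue
        labels, values = [], []
        for r in recs:
            if np.isnan(ab[r.index]):
                continue
            at = sum(ch in "AT" for ch in r.variant) / len(r.variant)
            labels.append(round(100 * at))
            values.append(ab[r.index])
        values = np.asarray(values)
        labels = np.asarray(labels)
        summary = (
            pd.DataFrame({"at_percent": labels, "abundance": values})
            .groupby("at_percent")["abundance"]
            .agg(["count", "mean", "std"])
            .reset_index()
        )
        grouped = [values[labels == g] for g in np.unique(labels)]
        usable = [g for g in grouped if len(g) >= 2]
        if len(usable) < 2:
            results[cls] = ATContentResult(
                summary, None, None, None,
                notice="fewer than two groups with >= 2 members; comparison skipped",
            )
            continue
        f_stat, p_val = sps.f_oneway(*usable)
        tukey = pairwise_tukeyhsd(values, labels)
        tukey_df = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        results[cls] = ATContentResult(summary, float(f_stat), float(p_val), tukey_df)
    return results


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def per_position_error_rates(
    reads: ReadSet, pool: VariantPool
) -> tuple[pd.DataFrame, int]:
    """Align each read to its assigned reference and tally substitution,
    insertion, and deletion events per reference position.

    Rates are events per assigned read at that position, aggregated over
    the whole pool (all references share the template length).  Returns
    ``(rate_matrix, n_excluded)`` where excluded reads could not be
    assigned by barcode.
    """
    lo, hi = pool.barcode_interval
    exact = {r.barcode: r.index for r in pool.records}
    barcodes = [r.barcode for r in pool.records]
    m = pool.layout.total_length
    events = np.zeros((m, 3))  # substitution, insertion, deletion
    n_assigned = 0
    excluded = 0
    for read in reads.reads:
        bc = read[lo:hi]
        idx = exact.get(bc)
        if idx is None and len(bc) == hi - lo:
            dists = [hamming_distance(bc, b) for b in barcodes]
            dmin = min(dists)
            if dmin <= 1 and dists.count(dmin) == 1:
                idx = dists.index(dmin)
        if idx is None:
            excluded += 1
            continue
        ref = pool.records[idx].template
        n_assigned += 1
        if read == ref:
            continue
        aln = edlib.align(read, ref, task="path")
        pos = 0  # reference coordinate
        for num, op in _CIGAR_RE.findall(aln["cigar"]):
            num = int(num)
            if op == "=":
                pos += num
            elif op in ("X", "M"):
                events[pos : pos + num, 0] += 1
                pos += num
            elif op == "I":  # read bases absent from the reference
                events[min(pos, m - 1), 1] += num
            elif op == "D":  # reference bases absent from the read
                events[pos : pos + num, 2] += 1
                pos += num
    rates = events / n_assigned if n_assigned else events
    df = pd.DataFrame(
        rates,
        columns=["substitution", "insertion", "deletion"],
        index=pd.RangeIndex(m, name="position"),
    )
    return df, excluded
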
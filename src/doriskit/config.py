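"""Run configuration, seed derivation, and fixture generation.

One master seed drives every stochastic stage; each stage draws from a
substream derived deterministically from ``(master_seed, label)`` so that
pipelines are reproducible stage by stage and insensitive to reordering.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import addresses as addr_mod
from . import codec as codec_mod
from .sequences import FileRecord, write_fasta
from .simulate import AccessParams, Database


def seed_for(master_seed: int, label: str) -> int:
    """Deterministic 31-bit substream seed for a labeled operation."""
    return (master_seed ^ zlib.crc32(label.encode())) & 0x7FFFFFFF


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(seed_for(master_seed, label))


class CodecConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    codeword_length: int = Field(default=4, ge=4, le=12)
    index_codewords: int = Field(default=5, ge=0)
    payload_capacity_nt: int = Field(default=160, gt=0)
    max_homopolymer: int | None = Field(default=None, ge=1)


class AddressConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_candidates: int = Field(default=10_000, ge=0)
    threshold: int = Field(default=6, ge=0)
    gc_min: float = Field(default=0.40, ge=0.0, le=1.0)
    gc_max: float = Field(default=0.60, ge=0.0, le=1.0)
    max_homopolymer: int = Field(default=3, ge=1)
    payload_sample: int = Field(default=10_000, ge=1)


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    separation_probability: float = Field(default=0.5, ge=0.0, le=1.0)
    per_access_retention: float = Field(default=0.87, ge=0.0, le=1.0)
    ivt_hours: float = Field(default=8.0, ge=0.0)
    elution_efficiency: float = Field(default=1.0, ge=0.0, le=1.0)
    temperature_celsius: float = Field(default=25.0, gt=-273.15)
    lock_melt_celsius: float = Field(default=45.0, gt=-273.15)
    lock_leak_fraction: float = Field(default=0.05, ge=0.0, le=1.0)

    def to_access_params(self) -> AccessParams:
        return AccessParams(
            separation_probability=self.separation_probability,
            per_access_retention=self.per_access_retention,
            ivt_hours=self.ivt_hours,
            elution_efficiency=self.elution_efficiency,
            temperature_celsius=self.temperature_celsius,
            lock_melt_celsius=self.lock_melt_celsius,
            lock_leak_fraction=self.lock_leak_fraction,
        )


class PoolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    barcode_length: int = Field(default=8, ge=4)
    n_reads: int = Field(default=100_000, ge=0)
    substitution_rate: float = Field(default=1e-3, ge=0.0, le=1.0)
    insertion_rate: float = Field(default=2e-4, ge=0.0, le=1.0)
    deletion_rate: float = Field(default=5e-4, ge=0.0, le=1.0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = Field(default=0, ge=0)
    codec: CodecConfig = Field(default_factory=CodecConfig)
    addresses: AddressConfig = Field(default_factory=AddressConfig)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    pool: PoolConfig = Field(default_factory=PoolConfig)
    output_dir: str = "."

    @model_validator(mode="after")
    def _check_gc_range(self) -> "RunConfig":
        if self.addresses.gc_min > self.addresses.gc_max:
            raise ValueError("addresses.gc_min must not exceed addresses.gc_max")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML config; unknown keys are rejected, defaults filled in."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def make_fixture_database(
    n_files: int,
    strands_per_file: int,
    L: int = 4,
    seed: int = 0,
    *,
    copies_per_strand: int = 100,
    fasta_path: str | Path | None = None,
) -> Database:
    """A synthetic multi-file database: random payloads encoded at codeword
    length ``L`` under mutually orthogonal designed addresses."""
    if n_files <= 0 or strands_per_file <= 0:
        raise ValueError("sizes must be positive")
    spec = codec_mod.make_codeword_table(L)
    candidates = addr_mod.generate_candidates(
        max(4 * n_files, 32), seed_for(seed, "fixture-addresses")
    )
    survivors = addr_mod.mutual_orthogonality_filter(candidates)
    if len(survivors) < n_files:
        raise ValueError("address design yielded too few orthogonal addresses")
    rng = rng_for(seed, "fixture-payloads")

    from . import codec as _codec
    from .sequences import build_ssdsdna

    db = Database(rng_seed=seed_for(seed, "fixture-db"))
    records = []
    for fi in range(n_files):
        address = survivors[fi].sequence
        n_bytes = strands_per_file * spec.data_bytes_per_strand
        payload = rng.integers(0, 256, size=n_bytes, dtype=np.uint8).tobytes()
        templates, _ = _codec.encode(payload, spec, address)
        layout = _codec.strand_layout_for(spec, len(address))
        frec = FileRecord(address=address)
        for si, tpl in enumerate(templates):
            sid = f"f{fi}s{si}"
            strand = build_ssdsdna(tpl, layout=layout)
            frec.add(sid, strand, copies_per_strand)
            records.append(
                (
                    sid,
                    {
                        "file": str(fi),
                        "address": address,
                        "copies": str(copies_per_strand),
                    },
                    tpl,
                )
            )
        db.files[address] = frec
    if fasta_path is not None:
        write_fasta(fasta_path, records)
    return db
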
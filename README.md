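# doriskit

A design toolkit and stochastic simulator for **overhang-addressed DNA data
storage**: double-stranded DNA templates that carry a single-stranded 3'
overhang used as a physical file address, read non-destructively by T7
in-vitro transcription, and manipulated in storage by toehold-mediated
strand displacement.

## The science in brief

Most DNA storage schemes retrieve files by PCR, which requires the file
address (primer site) to be absent from every payload in the database —
otherwise the primer mis-primes inside payloads and produces truncated
products. That coupling between address design and payload content shrinks
the usable address space as payloads grow.

The alternative modelled here stores each file as **ss-dsDNA**: a duplex
template whose last 20 nt stay single-stranded after a single-primer
fill-in reaction, because the common primer-binding site is inset 20 nt
from the 3' end. Access is physical hybridization of a bead-linked oligo
to that exposed overhang, at a temperature where the duplex payload never
melts. Internal payload sequence is therefore invisible to the access
chemistry, and address design decouples from database content.

`doriskit` implements the full stack around that idea:

- **Strand model** (`sequences`): template layout, single-primer extension
  geometry, overhang state machine (exposed / locked / blocked / renamed).
- **Codec** (`codec`): one byte per fixed-length codeword, 5 big-endian
  index codewords per strand, density `(160 − 5L)/L` bytes per 160 nt of
  payload capacity, and database capacity scaling with the number of
  usable addresses.
- **Address design** (`addresses`): GC/homopolymer-screened 20-mer
  candidates, greedy mutual-orthogonality filtering at Hamming distance
  ≥ 6 (including reverse complements), and a Monte Carlo survey that
  contrasts PCR-style screening (addresses must also avoid every 20-mer
  window of every payload) with overhang-style screening (mutual
  orthogonality only).
- **Thermodynamics** (`thermo`): nearest-neighbor duplex free energies and
  an equilibrium binding model `K = exp(−ΔG°/RT)` for capture fractions.
- **Simulator** (`simulate`): per-copy binomial/Poisson accounting of
  separation, transcription, and return; repeat-access retention; and the
  lock / unlock / rename / delete toehold operations.
- **Pool + NGS readout** (`pool`): a 1088-member promoter-variant library
  (1024 upstream 5-mers × 64 downstream 3-mers), a seeded read simulator
  with substitution/indel errors, barcode demultiplexing, normalized
  abundance, quartile position-frequency matrices, A/T-content ANOVA with
  Tukey–Kramer post-hoc tests, and per-position error profiling from
  edit-distance alignments.
- **CLI** (`doriskit ...`): encode, decode, design-addresses, survey,
  thermo, simulate, pool-design, simulate-reads, analyze-reads, fixtures.

## Worked example

```python
import numpy as np
from doriskit import (
    make_codeword_table, encode, decode, density,
    generate_candidates, mutual_orthogonality_filter,
    build_ssdsdna, overhang_of,
    Database, AccessParams, repeat_access, min_initial_copies,
)
from doriskit.sequences import FileRecord

# 1. design mutually orthogonal addresses
cands = generate_candidates(500, seed=42)
addrs = mutual_orthogonality_filter(cands)
address = addrs[0].sequence          # 'ATGCCTAGAAGTGTGTGATC'

# 2. encode a message (1 byte per 4 nt codeword, density 35 B / 160 nt)
spec = make_codeword_table(4)
strands, manifest = encode(b"Hello, DNA storage!", spec, address)
len(strands)                         # 1
density(4)                           # 35.0
decode(strands, spec, manifest["payload_length"])
# b'Hello, DNA storage!'

# 3. single-primer extension exposes the 20 nt address as a 3' overhang
s = build_ssdsdna(strands[0])
overhang_of(s)                       # 'ATGCCTAGAAGTGTGTGATC'

# 4. simulate five access cycles (default retention 0.87 per cycle)
frec = FileRecord(address=s.address)
frec.add("s0", s, 1000)
db = Database(files={s.address: frec})
_, table = repeat_access(db, s.address, 5, AccessParams(),
                         np.random.default_rng(0))
print(table.round(1))
#        ATGCCTAGAAGTGTGTGATC
# cycle
# 0                     100.0
# 1                      86.5
# 2                      74.8
# 3                      66.1
# 4                      55.9
# 5                      49.3

min_initial_copies(5, 0.87)          # 2
```

The same pipeline is available from the shell:

```bash
doriskit design-addresses --n 1000 --seed 42 --out addrs.fasta
doriskit encode --in message.bin --address ATGCCTAGAAGTGTGTGATC --out strands.fasta
doriskit decode --in strands.fasta --manifest strands.fasta.manifest.json --out out.bin
doriskit survey --mode pcr --codeword-length 4 --db db.fasta --out survey.csv
```

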
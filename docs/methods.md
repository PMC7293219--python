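# Methods note

This note records the modelling assumptions, parameter calibration, and
numerical design choices behind `doriskit`. Everything here is the
package's own convention; where a quantity is calibrated rather than
derived, the calibration target is stated explicitly.

## 1. Strand model

A storage template is a single strand partitioned (5'→3') into payload,
a 23 nt promoter region, and a 20 nt address. The promoter region embeds
the reverse complement of the common primer `TCTGCTCTGCACTCGTAATAC`, so a
single primer anneals there and polymerase fill-in copies everything 5'
of the site. Because the address lies 3' of the primer site, it is never
copied: the product is a duplex with a 20 nt single-stranded 3' overhang
(ss-dsDNA). `build_ssdsdna` demands exactly one primer site, inside the
promoter interval — zero or ambiguous sites are hard errors, since the
fill-in geometry (and hence the overhang) would be undefined.

The default layout is 160 nt total (117 payload + 23 promoter + 20
address). The codec produces longer templates (payload capacity 160 nt,
total 203 nt) because the density model counts bytes per 160 nt of
*payload*; both layouts flow through the same `TemplateLayout` machinery
and both leave exactly a 20 nt overhang, which is asserted across a
length series in tests.

Strand state is explicit: `EXPOSED` (overhang available), `LOCKED`
(lock annealed over the address, presenting a 30 nt toehold),
`BLOCKED` (deleted; nothing presented), `RENAMED` (rename oligo presents
a different address), `BEAD_BOUND` (currently captured). The
`effective_address` of a strand — what an access oligo can actually see —
is derived from state plus attachments, never stored independently, so
the state machine cannot drift out of sync with the sequence bookkeeping.

## 2. Codec

One codeword of length `L` stores one byte; a strand holds 5 index
codewords (big-endian base-256 strand index) followed by data codewords.
The codeword table is built by lexicographic filter-then-take-first:
enumerate all `4^L` words in lexicographic order, drop words violating
constraints (e.g. homopolymer caps), keep the first 256. This is
deliberately the simplest deterministic table construction — the point
of the codec module is the density/capacity arithmetic, not channel
coding.

- Information density: `density(L) = (160 − 5L)/L` bytes per 160 nt of
  payload capacity (the 5L term is the index overhead).
- Database capacity: `capacity(n, d) = 10⁹ · n · d / 10` bytes — `n`
  usable addresses, `10⁹` strands per file, a 10× physical replicate
  factor. Both factors are configurable; the defaults define the
  reference operating point used in the capacity curves.

Decoding sorts strands by their decoded index, so input order is
irrelevant; an unknown codeword raises an error naming the offending
slot rather than silently mis-decoding.

## 3. Address design

Candidates are random 20-mers passing GC fraction 0.40–0.60 and maximum
homopolymer run 3. The mutual-orthogonality filter is greedy: accept a
candidate iff its Hamming distance to every accepted address *and* every
accepted address's reverse complement is ≥ 6. Greedy acceptance is
order-deterministic, which makes the filter exactly reproducible and
testable against a brute-force oracle.

Two survey modes model the two retrieval chemistries:

- **Overhang mode**: mutual orthogonality only. Survivor counts are
  therefore invariant to codeword length and database content — the
  design-space decoupling that motivates the architecture.
- **PCR mode**: additionally reject any candidate within Hamming
  distance < 6 of any 20-mer window of any database strand (windows of
  both the strand and its reverse complement, i.e. both duplex strands
  melt during PCR). With random payloads this collapses the address
  space as codeword diversity falls: at the desk scale used in the
  acceptance suite (10⁴ candidates, 10⁵ strands), survivors drop from
  9046 at L = 12 to 0 at L = 4 while overhang-mode survivors stay at
  9593 throughout.

### Numerical design

20-mers are packed 2 bits/base into `uint64`; Hamming distance is
computed as `popcount((x ^ y) | ((x ^ y) >> 1) & 0x5555…)`. The payload
conflict screen is an exact pigeonhole index: split each 20-mer into two
10-mer halves; any match with ≤ 5 mismatches has a half with ≤ 2
mismatches, so probing the 436 ≤2-mismatch XOR deltas of each query half
against sorted half tables finds all candidates, which are then verified
with the full packed Hamming kernel. This is exactly equivalent to the
brute-force scan (asserted in tests) and ~50× faster on this
interpreter, which is what makes the desk-scale acceptance run fit in a
few minutes.

## 4. Thermodynamics

Duplex formation free energy uses unified nearest-neighbor ΔH/ΔS stack
parameters with terminal initiation corrections;
`K = exp(−ΔG°/RT)` with `R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹`. Two bound-
fraction forms are provided: a clipped-linear form `min(K·[oligo], 1)`
(adequate far from saturation) and the saturating isotherm
`K·c / (1 + K·c)`. They agree to first order for `K·c ≪ 1`; the
saturating form is the physically bounded default for trend predictions
(capture improves with oligo length, degrades with temperature).

## 5. Simulator calibration

All stochastic steps are integer-copy binomial/Poisson draws, so copies
are conserved exactly through a lossless separate → return round trip.
The defaults are calibrated to two observations: roughly half of a file
is captured per separation, and about half of the file survives five
full access cycles. That fixes:

- `separation_probability = 0.5`
- per-cycle retention `0.87 = 0.5^(1/5)` (so five cycles retain ≈ 49.8%)
- captured-strand survival `0.74 = 1 − (1 − 0.87)/0.5`, spread over the
  default 8 h transcription as an hourly loss rate `1 − 0.74^(1/8)`
- elution efficiency 1.0.

The decomposition is chosen so the *expected* per-cycle retention is
exactly 0.87 (`0.5·0.74 + 0.5`), which is what the stochastic-
calibration acceptance test checks (mean over ≥ 1000 replicates within
3 standard errors of 0.498).

`min_initial_copies(n, r)` returns the smallest copy count whose
expected survivorship after `n` accesses is at least one copy within a
1% relative slack: `ceil((1 − 0.01)/rⁿ)`. At the reference operating
point (n = 5, r = 0.87, survivorship 0.4985) this gives 2; without the
slack the bound would round up to 3 on a 0.3% shortfall, which
over-states the requirement given the precision of the retention
calibration.

### Toehold operations

- **Lock**: 50 nt = 30 nt toehold + 20 nt address complement. Annealing
  below 45 °C is modelled as leaky (5% per-copy spurious capture);
  at/above 45 °C the lock is complete. During access above 45 °C the
  lock melts off and the strand answers to its designed address again.
- **Key/unlock**: the full 50 nt complement of the lock displaces it via
  the toehold at ordinary temperatures; a mismatched key is a warning,
  not an error, and leaves the file locked.
- **Rename**: 40 nt = new address + old-address complement; the
  presented single-stranded segment *is* the new address, so capture
  logic stays uniform (`capture ⇔ revcomp(oligo) == effective address`).
  5'/3' polarity of the presented segment is not modelled.
- **Delete**: the exact 20 nt complement of the effective address blocks
  it; blocked strands answer to nothing.

PCR-mode separation additionally scans payloads (both orientations) for
internal primer sites and records each as a truncated-product event in
the database log — the failure mode the overhang architecture avoids.

## 6. Variant pool and sequencing readout

The promoter-variant library enumerates every 5-mer immediately upstream
of the promoter (in the untranscribed overhang side, 1024 strands) and
every 3-mer immediately downstream (inside the transcribed payload, 64
strands): 1088 distinct 160 nt strands. Since upstream variants are not
transcribed, every strand carries an 8 nt payload barcode (pairwise
Hamming distance ≥ 2, greedy seeded construction) identifying its
variant; demultiplexing tolerates one mismatch and leaves ties
unassigned.

The read simulator draws reads multinomially, weighted by per-variant
transcription efficiency for post-IVT reads and uniformly for the
pre-library, with independent per-base substitution/insertion/deletion
errors (defaults 10⁻³ / 2×10⁻⁴ / 5×10⁻⁴). Analysis outputs:

- normalized abundance = post/pre read-count ratio (NaN when pre = 0);
- quartile position-frequency matrices over the variant positions
  (ascending abundance, ties broken by sequence for determinism);
- A/T-content group comparison: one-way ANOVA plus Tukey–Kramer pairwise
  tests per variant class;
- per-position error rates from edit-distance (edlib) alignments of each
  read to its demultiplexed reference.

**Indel attribution caveat.** Edit-distance alignment localizes an indel
only up to equal-cost alternatives: a deletion in a homopolymer run can
be reported at any position of the run, and two adjacent substitutions
forming a swap (`AB → BA`) tie in cost with a deletion+insertion pair.
Per-position recovery is therefore asserted for substitutions, while
indels are validated in aggregate with the spurious-event rate bounded
by the adjacent-double-substitution pair rate. This is a property of any
minimum-edit-distance aligner, not of this implementation.

## 7. Reproducibility

One master seed drives every stochastic stage through
`seed_for(master, label) = (master ^ crc32(label)) & 0x7FFFFFFF`, so
pipelines are reproducible stage by stage and insensitive to stage
reordering. Property-based tests run derandomized with a fixed profile;
the acceptance suite pins every seed and states every tolerance
(3 standard errors for the calibration mean, 5σ binomial bands for
per-position error recovery, exact equality for combinatorial facts).

Problem sizes in the acceptance suite (10⁴ candidates × 10⁵ strands for
the survey curve, 10⁴ reads for error recovery, 10³ replicates for the
calibration check) are chosen to resolve the qualitative claims with
comfortable statistical margin while completing in minutes on one CPU.
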
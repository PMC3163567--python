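# Methods

This note documents the models and procedures implemented in `readforge`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic experiments show.

## Read simulation

**Window sampling.** Fixed-length windows (default 350 nt) are drawn from
contigs of at least 1 Mb, restricted to N-free start positions, uniformly
with replacement over all eligible positions pooled across contigs. The
sampling scheme (uniform, with replacement, forward strand only) is a
package choice; provenance records carry a strand field so strand
randomisation can be added without changing the truth-name format.
Coordinates are 0-based half-open internally; insert lengths (equivalently
adapter start positions) are reported 1-based.

**Molecule construction.** For each window and each insert length *L* in
the sweep, the molecule is the window's first *L* bases. The forward read
is molecule + adapter + poly-A pad truncated to the read length; the
reverse read is the reverse-complemented molecule + adapter + pad. Both
adapters default to the 61-nt Illumina paired-end adapter (identical for
both mates) and are independently configurable. With the defaults —
10,000 windows, inserts 1..350, 101-cycle reads — a run emits exactly
3,500,000 molecules (pairs). The package counts *pairs*: each molecule
yields one forward and one reverse read.

**Error injection.** Errors are substitution-only, independent across
cycles within a read, drawn per (cycle, true base) from the profile's
rate; the substituted base is uniform over the three alternatives (a full
substitution matrix would be a straightforward extension; nothing in the
implemented experiments requires one). No indels, no phasing or
intensity-level modelling, no chimera or duplicate simulation.

**Quality models.** `position_average` assigns every base of a given type
at a given cycle the cell's mean quality — errors are invisible in the
qualities. `error_informative` adds a uniform integer jitter in
`{0..10}` for correct bases and subtracts one for errors, so quality
carries information about error without being deterministic. Simulated
qualities are clamped to `[2, 41]`, the platform's printable range.

**Synthetic profiles.** `make_synthetic_profile` interpolates a rate from
`e_start` (cycle 1) to `e_end` (last cycle), linearly or geometrically,
identical across bases by default, with `mean_q = round(-10 log10 rate)`
clamped to `[2, 41]`. The standard test condition is 0.1% rising to 5%
over 101 cycles — a plausible modern-ish run; real profiles from specific
instruments rise further (to ~10%) in the final cycles and differ by
base, which is why error-reduction *factors* measured here are conditions
of this generator, not instrument constants.

## Pair merging

**Candidate scan.** For candidate insert *L*, the reverse complement of
the reverse read is placed so both reads' adapters would start at
position *L*. Scored positions are (a) the read-read overlap, weighted by
`min(q_fwd, q_rev)`, and (b) for `L < read_len`, each read's tail against
its expected adapter-then-pad sequence, weighted by the read base's own
quality. `N` bases carry zero weight. Identity is the weighted match
fraction; at uniform qualities it reduces to plain identity. The
`min(q1,q2)` weighting was chosen (the weighting scheme is not uniquely
determined by the verbal description "quality score adjusted sequence
identity") so that low-quality mismatches cannot veto a merge.

**Admissibility.** A candidate needs a read-read overlap of at least 11
nt *or* `L < read_len` (adapter positions at identical starts in both
reads supply evidence instead). The second clause is what lets 1–4 nt
adapter dimers be *detected* — their read-read overlap is far below 11 nt,
yet their candidates score ~1.0 on adapter evidence — and then discarded
(`min_merged_len = 5`). Without it the dimer class could never be
assigned.

**Decision.** The highest-identity admissible candidate wins; exact ties
go to the smaller insert (more positions explained by adapter).
`identity < 0.90` → unmerged; winning `L < 5` → dimer; otherwise the
consensus over the insert is emitted, copying single-covered positions
verbatim and combining double-covered ones.

**Consensus call.** Per-read likelihoods are `1 - eps` for the observed
base and `eps/3` for each other base (`eps = 10^(-q/10)`); the posterior
over the four bases is the product under a uniform prior. Two
conventions matter and are fixed here: (1) `eps` is clamped at 3/4, so
quality 0 — like `N` — is uninformative rather than "certainly wrong"
(an unclamped `eps = 1` would make two agreeing Q0 bases call a *third*
base); (2) the consensus quality is `floor(-10 log10(1 - posterior))`,
truncated rather than rounded, capped at 60 — so two agreeing Q20 bases
give Q44 (exact value 44.68). Argmax ties prefer the forward read's
base, then the reverse read's, then alphabetical order; a position where
both reads show `N` emits `N` at quality 0. One degenerate corner is
accepted: two *disagreeing* quality-0 observations fall back to the
uniform prior and report quality 1, which no posterior rule can place
below `max(q1, q2) = 0`.

**Measured behaviour.** On ~50,000 simulated pairs (rising 0.1→5%
profile, inserts 5..101), merging reduces the per-base error rate by a
factor of ~21 under error-informative qualities and ~2.8 under
position-average qualities (seed-dependent in the second decimal). The
ordering — informative ≫ position-average — is structural: when reads
disagree, informative qualities tell the posterior which observation to
trust. The factors themselves depend on the profile; with a different
run's profile they would differ, which is why the test suite asserts the
ordering and a conservative ≥2x bound for the informative model rather
than specific factors.

## Filters

* **Entropy** — mononucleotide Shannon entropy over `{A,C,G,T}` (Ns
  excluded), normalised by 2 bits, cutoff 0.85. The estimator behind the
  published cutoff is not fully specified anywhere we know of
  (mono- vs di-nucleotide, normalisation), so the definition here is the
  simplest one consistent with a [0,1] scale; on a different estimator
  the same numeric cutoff would select differently. A three-letter
  repeat like `GACGAC…` scores `log2(3)/2 ≈ 0.79` and fails the cutoff.
* **Quality** — pass iff at most `floor(len/20)` bases are below Q15.
  The floor operationalises "one outlier per 20 cycles"; reads shorter
  than 20 cycles get no allowance.
* **Chastity** — per cycle, the called (max) channel must be ≥1.5x the
  runner-up, boundary inclusive; a zero runner-up passes iff the maximum
  is positive. Presets: first 12 cycles / 0 outliers, or 25 / 1. The
  intensity input is a toy `(cycles, 4)` matrix interface — real
  intensity files are instrument-specific and out of scope.
* **Tag** — Hamming distance of the read prefix to the tag, pass at ≤1
  substitution by default; reads shorter than the tag fail with a
  distinct statistic (infinity). `N` is counted as a mismatch.
* **Chimera screen** — ungapped placement of each oligo (both
  orientations) and each ordered oligo-oligo junction against the read;
  flag when aligned coverage ≥0.8 of the read at ≥0.9 per-aligned-base
  identity. Each junction side uses the shift maximising
  `matches − 0.9·aligned` — a screen-grade heuristic, not an exhaustive
  joint optimum, and deliberately not a reimplementation of TagDust's
  statistics. At these thresholds, 10,000 random 101-mers produce zero
  false flags against the paired-end adapter.

Filters compose in a configurable order (default tag → chimera → entropy
→ quality), short-circuiting at the first failure; per-read verdicts and
a count summary are reported so the order's effect is visible.

## Error-count spectrum

The observed fraction of reads with exactly *k* mismatches is compared
with a binomial expectation whose per-base rate *p* is solved from the
observed one-error fraction at read length *L* (the map `p ↦ L·p(1−p)^(L−1)`
is increasing on `[0, 1/L]`; solved by bisection, clamped at `1/L`).
This independence extrapolation is the documented modelling choice. With
independently injected errors the observed spectrum matches it; with a
90/10 mixture of clean (0.1%/cycle) and noisy (5%/cycle) reads —
emulating clusters that accumulate error through proximity to a
neighbour — the observed two-error fraction exceeds the extrapolation
several-fold.

## Profile estimation and recovery

`build_profile_from_truth` counts mismatches per (cycle, true base) over
reads with known truth — the spike-in workflow. The recovery experiment
simulates 50,000 reads from a known profile and checks every rate cell
within `4·sqrt(p(1−p)/n_cell)`, where `n_cell` is that cell's number of
opportunities (the proper binomial 4σ band; with a fixed random truth
template each cell at a given cycle receives the full 50,000
observations for its template base and none for the others).

## Mapping evaluation

Per insert length: mapped (not unmapped), unique (MAPQ ≥ 20), correct
(same contig, expected orientation, 5' start within ±5 nt of the
position implied by the truth window — forward records at the window
start, reverse-mapped records at `start + insert − aligned_length`).
The tolerance absorbs soft-clip shifts that real mappers introduce when
adapter bases are present; tolerance 0 restores the strict check. Only
primary alignments are scored; unparsable names are counted, not fatal.
External mappers are consumed as black boxes through SAM.

## Problem sizes and determinism

All stochastic operations take explicit seeds; a single pipeline seed is
split per stage by hashing, so whole runs reproduce bit-identically
(gzip output is written with a zeroed timestamp for this reason). The
standard experiment sizes used throughout — 50,000 pairs for the merge
experiment, 50,000 reads for profile recovery, 20,000 for the spectrum,
the full 3.5 M-pair sweep for the simulator count — were chosen as the
smallest sizes at which the binomial bands above are meaningfully tight.

## What the synthetic data does not show

The reference generator produces i.i.d. bases: no repeats, no
low-complexity tracts, no real genomic structure. Consequences: merge
false-positive rates and mapping uniqueness here are optimistic relative
to real genomes (repeats create genuine ambiguity); the entropy filter's
false-positive rate on real genomic reads (which contain true
low-complexity sequence) is not measured by these tests; and
error-reduction factors are tied to the synthetic profile, not to any
particular instrument run. The error model is substitution-only and
independent across cycles — clustered error appears only where tests
construct it explicitly as a mixture.
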
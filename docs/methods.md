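# Methods

## The motif model

A G-quadruplex motif (G4-motif) is modelled as a chain of maximal
guanine runs on one strand:

* every run has at least `min_run = 3` consecutive G's (literal G only —
  no mismatches inside runs);
* consecutive runs are separated by loops of `min_loop = 1` to
  `max_loop = 12` nucleotides (loops may contain any base, including
  one- or two-G stretches and IUPAC ambiguity codes);
* a motif has at least `min_runs = 4` runs and spans at most
  `max_len = 109` bp.

The extended loop range (up to 12 nt rather than the 7 nt used in many
genome-wide surveys) deliberately includes the long-loop quadruplexes
that are common in promoter regions.  Because runs are *maximal*, a
motif necessarily starts at a run start and ends at a run end, and
adjacent runs always have a loop of at least one base between them
(`min_loop = 0` is unreachable by construction).

**Selection rule.** Candidate chains can nest and overlap; the scanner
reports a deterministic, mutually non-overlapping set by a greedy
leftmost-maximal sweep: open a motif at the first run that begins a
valid chain, extend through every subsequent run while loop bounds hold
and the total span stays ≤ `max_len`, emit, and resume at the next
unconsumed run.  If including the next run would exceed `max_len`, the
motif is emitted without it and scanning resumes *at* that run, so the
dropped run can still seed a new motif.  The test suite proves this
greedy rule equivalent to exhaustive substring enumeration followed by
leftmost-then-longest non-overlapping selection (`tests/oracles.py`).

Both strands are scanned; minus-strand motifs (C-run chains on the plus
strand) are projected to plus-strand coordinates and kept as distinct
motifs.  For counting and per-feature occupancy the two strands are kept
separate; for every SNP-overlap or subtraction computation the projected
intervals are flattened first, so an antiparallel overlap is never
counted twice.

## Coordinates

Everything internal is 0-based half-open; a SNP at position *p* overlaps
[*s*, *e*) iff *s* ≤ *p* < *e*.  VCF and the two-column SNP TSV are
1-based and converted at the I/O boundary only.  Promoter windows
("prom500") are the 500 nt immediately upstream of the TSS:
[tss−500, tss) on the plus strand, [tss+1, tss+501) on the minus strand.
Windows clipped at a chromosome edge are retained and flagged, and all
densities use the true clipped lengths so per-kb values stay unbiased.

## Disruptive guanines

Within a motif with exactly four G-runs, guanines whose substitution is
predicted to abolish quadruplex formation are: all G's of a 3-nt run,
the 2nd and 3rd G of a 4-nt run, and the middle G of a 5-nt run; runs of
six or more contribute no disruptive position.  Motifs with a fifth run
are excluded — the extra run is a "spare tire" that can replace a broken
one.  Run-internal offsets are mirrored for minus-strand motifs so the
rule applies in the structural orientation (the rule happens to be
palindromic within a run, so mirroring changes nothing, but it is
implemented explicitly).  Disruptive and non-disruptive SNP densities
are per-position counts restricted to G-run positions; loop positions
belong to neither class.

## Randomization tests and empirical significance

Three null models share one significance rule.  The empirical p is the
plain ratio r/n of randomizations at least as extreme as the
observation; ties count toward both tails, so `p_higher + p_lower ≥ 1`,
and a p of 0 is formatted as "< 1/n" while stored as 0.0.  The
conservative (r+1)/(n+1) variant is deliberately not the default, to
keep the reported quantity exactly the ratio of randomization outcomes.

1. **Length-matched enrichment** (motif density): each iteration draws
   N random regions whose lengths are resampled from the feature
   lengths, placed uniformly over valid positions genome-wide (regions
   more than 50% N are redrawn, at most 100 times), scans them on both
   strands and records the pooled per-kb density.  Defaults: 500
   iterations; 500 regions for promoter-like features, 50 for 6-kb
   eRNA-like features.  The pooled statistic (total motifs / total kb)
   is the default; the per-region mean is available as an option.
2. **Per-chromosome fragment resampling** (SNP density): targets are
   flattened, and each iteration resamples one fragment of identical
   length per flattened piece *from the same chromosome*, pooling SNP
   counts.  Default 10,000 iterations.
3. **GC-matched comparison** (motif polymorphism): each of 500
   iterations draws 100 motifs without replacement and pairs them with
   random regions matched to each motif's length and GC (tolerance
   0.02, widening by 0.02 after every 1,000 failed draws up to 0.10;
   each widening is logged; failure at the cap is an error).  The
   reported p is the fraction of iterations in which the random regions
   were strictly denser than the motif sample; with zero SNPs everywhere
   all iterations tie and the p is 0 — a documented consequence of the
   strict inequality, not a significance claim.

Every operation is a pure function of (inputs, seed).  One root seed
derives stage generators through `rng_from(root, *labels)`, which seeds
a numpy `SeedSequence` with the root plus the CRC32 of each label, so
the full pipeline is reproducible from a single integer.

The rank-sum (Mann–Whitney) test for the promoter–eRNA co-occurrence
analysis is implemented in the package: when both samples have ≤ 12
observations the exact permutation distribution of the rank sum is
computed by subset-sum counting over doubled midranks (identical to
enumerating all C(n+m, n) assignments, and correct under ties);
otherwise the normal approximation with tie correction and a 0.5
continuity correction is used.  An external implementation is used only
as a cross-check in the tests.

## The synthetic-data generator

The generator emulates the study inputs at desk scale: a
multi-chromosome genome of IID bases at GC 0.42 (the genome-wide GC of
sheep), strand-aware 500-nt promoter windows, 6-kb eRNA intervals,
planted canonical motifs, Bernoulli SNPs and gene–eRNA associations.
Defaults were fixed once from the study system:

| parameter | default | rationale |
|---|---|---|
| `gc` | 0.42 | ovine genome-wide GC |
| `motif_rate_prom` | 1.0 /kb | ~40% of 500-bp promoters carry ≥ 1 motif (Poisson) |
| `motif_rate_erna` | 0.23 /kb | ~75% of 6-kb eRNAs carry ≥ 1 motif |
| `motif_rate_background` | 0.20 /kb | eRNA density is near background |
| `snp_rate_background` | 0.027 /bp | ~70 M SNPs on a ~2.6 Gb genome |
| `snp_rate_g4_multiplier` | 0.8 | motifs mildly depleted vs context |
| `snp_rate_disruptive_multiplier` | 0.75 | disruptive G's less polymorphic |
| `erna_length` | 6000 | eRNA intervals are 6 kb |
| `assoc_per_erna` | 1–5 | each eRNA associates to one or more genes |
| `cooccurrence_bias` | 0.15 | modest but detectable co-occurrence |

**Exact truth.** Planted motifs are written with a non-G/non-C guard
base on each flank and kept more than `max_loop` bases apart, so maximal
runs cannot fuse a plant with its context and two plants cannot chain.
With `scrub=True` every maximal G- or C-run of ≥ 3 bases outside planted
spans is broken by mutating every third base to A/T; the background then
contains no qualifying run on either strand and the scanner's output
equals the truth manifest *exactly* (set equality of coordinates, runs
and strands — verified by the acceptance suite on a 1 Mb genome with 200
plants).  Scrubbing slightly depletes long G/C homopolymers relative to
a real genome; it should be switched off for composition-sensitive
studies, in which case truth equals scan output only up to accidental
background motifs.

Associations are drawn so that
P(promoter G4 | eRNA G4) − P(promoter G4 | no eRNA G4) = *b* in
expectation while keeping the overall marginal near the promoter G4
frequency q: partners of G4-bearing eRNAs are G4-positive promoters with
probability q + b(1 − f), partners of G4-free eRNAs with that minus b
(f = eRNA G4 frequency).  An infeasible b for the realized marginals is
an error reporting the feasible range.

**What the generator does not emulate:** linkage disequilibrium,
mutation spectra, repeats, assembly gaps, CpG islands or any regional GC
structure, and transcribed gene bodies.  Passing tests therefore
demonstrate correctness of the computations and calibration of the
randomization machinery under a homogeneous genome — not robustness to
the compositional heterogeneity of real assemblies.  In particular,
GC-matching is much easier on an IID genome than on a real one, where
high-GC templates may exhaust the widening schedule.

## Validation designs and problem sizes

The acceptance suite (`tests/test_acceptance.py`, reproduced by
`scripts/acceptance.py`) uses these designs, chosen as the package's
validation conditions:

* scanner vs oracle: 1,000 random sequences, length ≤ 300, GC 0.3–0.7;
* planted recovery: 1 Mb genome, 200 plants, scrub on;
* disruptive rule: 10,000 random four-run motifs vs the closed form;
* null calibration: 200 replicates each, every replicate with its own
  freshly generated genome (and SNP field) so replicate p values are
  independent.  The calibration genome plants background motifs at
  1.2/kb and each replicate observes 40 non-overlapping windows of
  500–1,200 bp (~38 expected motifs): a sparser statistic would be
  dominated by ties, and homogeneous window lengths would leave the
  pooled count statistic discrete, both of which make the empirical p
  conservative rather than uniform.  The SNP calibration uses 20 one-kb
  targets on a 0.01/bp SNP field, 200 iterations per test;
* power: 100 replicates of 3× promoter enrichment (150 promoters,
  background 0.2/kb, 100 iterations); SNP depletion on 10 chromosomes
  with 50 kb of targets each at half the 0.01/bp background, 1,000
  iterations;
* parameter recovery: disruptive multiplier 0.5 over ~50,000 G-run
  positions; association bias 0.3 at 2,000 eRNAs with flags taken from
  the scanner, not the truth manifest.

## Numerical and degenerate-input choices

* Zero-length interval sets, empty samples, empty null distributions and
  all-N sequences are errors, not silent zeros.
* Chromosomes absent from the SNP set contribute density 0 without
  error; per-chromosome disruptive ratios with zero non-disruptive SNP
  density are reported as NaN and logged.
* Duplicate or overlapping intervals are merged before any length or
  count enters a denominator; permutation of interval lists never
  changes a density.
* Significance labels follow p < 0.05 (*), p < 0.01 (**), p < 0.001
  (***), NS otherwise.

## Known limitations

* The scanner implements the exact-grammar motif model only: no
  mismatched or bulged runs, no sliding-window propensity scores, and no
  score thresholds.
* One promoter per `gene_id` is assumed; alternative TSSs must be
  collapsed upstream.
* GO-term overrepresentation and assembly liftover are out of scope.
* The per-eRNA ratio statistic follows the "ratios of promoters of the
  genes associated to each eRNA" reading; the symmetric per-promoter
  view is not produced by the pipeline report.
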
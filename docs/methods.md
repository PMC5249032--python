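# Methods

This note documents the models and procedures implemented in srnakit, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices that were genuinely
open.

## Annotation waterfall

Reads are uppercased, U→T normalized and collapsed to unique sequences
with summed counts at load time; reads shorter than 18 nt or longer than
28 nt are discarded before annotation. Each retained unique read is then
assigned to the **first** matching tier:

1. structural noncoding RNA (rRNA/tRNA/snRNA/snoRNA) — exact substring,
   either strand;
2. transposons + protein-coding mRNA — exact substring, either strand;
3. mature miRNA catalog — full-length alignment of the read inside a
   catalog entry with at most `mirbase_max_mismatch` substitutions
   (default 2, no indels; set 0 for exact-only). The threshold is a
   convention for homolog matching, exposed as a parameter because no
   single value is canonical;
4. genome — exact substring, either strand;
5. unmapped.

Matching is computed per tier over the whole read set and resolved by
precedence afterwards, so reference insertion order cannot influence
assignments. Tier 3 keeps **all** matched catalog ids per read (needed
for family pooling); the category itself is decided by tier only.

Because tiers are exclusive, per-category totals sum exactly to the
library total — an invariant the tests assert per library. Reference
sets whose categories overlap biologically (a miRNA inside an annotated
transposon, say) are resolved by precedence, and a separate
"genome-mappable at any tier" figure is reported for comparison with
tallies that count categories independently. Transposons and mRNAs form
a single reference component and are therefore reported as one category.

The catalog matcher uses a pigeonhole seed prefilter (one of
`max_mm + 1` read chunks must occur exactly in the catalog), which makes
the substitution scan linear in practice for realistic library sizes.

## Quantification

RPTM (reads per ten million) is `count × 1e7 / N` with `N` the total
retained (length-filtered) reads of the library; a flag switches the
denominator to genome-mappable reads. With the default denominator,
ΣRPTM over all unique retained reads is exactly 1e7 per library.

Mature miRNA ids are collapsed to families by convention:
`<species>-miR<number><variant letters><-arm><*>` → `MIR<number>`
(e.g. `gma-miR156b-5p` → `MIR156`). Ids the convention cannot parse are
kept whole as singleton families with a warning; an explicit id→family
override map wins over the convention. Family counts pool raw member
counts per library (so a read matching several members of one family
contributes once per matched member — exact for the synthetic data,
where every mature sequence has one id). miRNA* entries (ids carrying a
trailing `*`) are excluded from family pooling by default and summarized
separately as star/mature mean-RPTM ratios; the ratio is flagged
undefined when the family has no mature signal.

Families are tiered on mean control-condition RPTM (configurable to the
all-library mean): high ≥ 100,000; moderate [10,000, 100,000); low
[1,000, 10,000); extremely low [0, 1,000). Every tier is closed at its
lower edge; "100,000 and above" fixes the convention and the other
boundaries follow it.

## Secondary structure and novel miRNA discovery

**Folding.** Precursor windows are folded by base-pair maximization: the
maximum-weight set of nested pairs (Watson-Crick weight 1, G:U weight
`gu_weight`, default 1) with a minimum hairpin loop of 3 nt, computed by
a Nussinov-style dynamic program vectorized over anti-diagonals. The
traceback is deterministic: the 5′-most unresolved position is settled
first, and a co-optimal pairing chooses the 3′-most partner. Base-pair
maximization was chosen over free-energy minimization because it is
dependency-free and exactly checkable against exhaustive enumeration of
all nested structures on short sequences (a property the test suite and
the acceptance script exercise on random sequences of length ≤ 18); a
thermodynamic folder can be plugged in behind the same interface.

**Candidate extraction.** Genome-tier reads with a summed count of at
least `min_read_count` (default 5 — singleton background reads carry no
processing evidence and are not worth folding) are mapped exactly to the
genome on both strands; reads with more than `max_loci` (default 5)
placements are set aside as repeat-derived. Around each locus a window
of ±150 nt is excised (clipped at chromosome ends, reverse-complemented
for minus-strand loci so the precursor is always in transcript
orientation).

**Duplex evaluation.** In a clean antiparallel duplex the partner offset
`q(i) + (i − mature_start)` is constant along the mature read. The
evaluation takes the fold's partners of the mature core (the read minus
its 2-nt 3′ overhang), determines the hairpin arm from the majority
partner side (failing candidates whose partners sit mostly inside the
read: "loop-spanning"), and considers every realized partner offset as a
candidate duplex register, keeping the register with the fewest
sequence-level mismatches (positions that can form neither a
Watson-Crick nor a G:U pair with their register partner). Scoring
mismatches at sequence level against a structure-implied register makes
the criteria robust to co-optimal traceback noise, which is substantial
under pair maximization on 321-nt windows. A candidate passes with ≤
`max_mismatch` (default 4) mismatches and no asymmetric bulge >
`max_bulge` (default 2) nt between consecutively paired positions. These
defaults express the community guidelines for plant miRNA annotation,
which the source criteria reference without fixing numbers; all are
configuration.

**miRNA\* validation.** The star region is the opposite duplex strand
shifted for 2-nt 3′ overhangs: `star_start = register − (L − 3)` for an
L-nt mature. A sequenced read is star evidence when it lies in the
precursor with both ends within ±2 nt of that region and was sequenced
at least `min_star_count` times across libraries (default 2: one stray
read at the right coordinates is indistinguishable from background
degradation). A novel call requires the duplex criteria **and** star
evidence; candidates with overlapping windows on the same strand merge
into one call keeping the most abundant mature. Calls are emitted in
genomic order, making the output deterministic.

## Differential expression

Counts are modeled negative-binomially with variance μ + φμ². A single
common dispersion φ is estimated by maximizing the conditional (qCML)
log-likelihood of the replicate splits given per-condition totals, after
scaling every library to the geometric-mean library size and rounding;
the 1-D search runs on log φ over [1e-6, 10] and returns 0 at the lower
boundary (under-dispersed data). Estimation requires at least one
condition with ≥2 replicates; otherwise a fixed dispersion must be
supplied.

The exact test conditions on the pooled total t of the two condition
sums after library-size equalization: the first-condition sum follows a
ratio of NB probability products (Binomial(t, n₁/(n₁+n₂)) exactly when
φ = 0, a limit the tests verify numerically), and the two-sided p-value
accumulates every outcome whose conditional probability does not exceed
the observed one. Computation is in log space throughout.

The reported log₂ fold change is pooled-RPTM arithmetic —
`log2(Σ stress / Σ control)` over replicate RPTM values — with a 0.5
pseudocount added to both sums only when one of them is zero;
both-zero features are undefined (NaN, never an exception) and
non-significant by construction. This arithmetic reproduces printed
per-family fold-change values from their per-library RPTM inputs to
within ±0.05 log₂ units, which a GLM-shrunken estimate would not.
Stringent calls require |logFC| ≥ 1 and BH-FDR < 0.05; a relaxed
fold-change-only call column is emitted alongside. The mean-abundance
column is log₂ counts-per-million of the pooled feature count and is
descriptive only.

This is a re-implementation of the classic small-replicate exact-test
scheme; library-size equalization uses total-count scaling rather than
quantile adjustment and dispersion is a single common value, so p-values
approximate rather than duplicate other implementations (a fixed-matrix
cross-check against the Bioconductor reference implementation asserts
identical logFC to 0.05, identical significance pattern and identical
p-value ranking). Under the simulated study conditions (2 vs 2
replicates, φ = 0.1, 500 features) the test's type-I error at nominal
0.05 is ≈ 0.04–0.05 and recovery of 4-fold effects with means ≥ 100
counts exceeds 95%.

## Target prediction and enrichment

The reverse complement of the miRNA is slid along each transcript with
no indels; at each offset, positions are classed as matched, wobble
(miRNA G opposite transcript U, or miRNA U opposite G) or mismatched.
The site score is `mismatches + gu_penalty × wobbles`, with
`gu_penalty = 0.5` by default (0 and 1 are supported); sites with score
≤ `max_mismatch` (default 3, i.e. "fewer than four mismatches") are
reported, best site per transcript first. The substitution-only scan is
deliberately exact against naive per-offset counting — whether the
original seed-weighted scanner counted wobbles as mismatches is not
reconstructible, so the operative mismatch filter is implemented with
the wobble policy exposed.

Enrichment is the standard one-sided hypergeometric over-representation
test on flat gene→term annotations (no hierarchy propagation), with
BH-FDR across terms.

## The synthetic-data generator

The generator emulates the study design end to end: 2 conditions × 2
replicate libraries (configurable), default depth 2×10⁶ reads each,
18–28 nt reads with a length distribution peaked at 21 and 24 nt, and a
toy genome carrying planted miRNA hairpins plus structural-ncRNA and
transposon/mRNA decoy features.

Each planted hairpin consists of a random 21-nt mature arm, a loop of
8–15 nt, a star arm built as the duplex complement of the mature with
2-nt 3′ overhangs on both strands and `duplex_mismatches` (default 2)
planted substitutions — chosen among bases that can form neither a
Watson-Crick nor a G:U pair, so a planted mismatch is a true mismatch —
and a perfectly complementary 20-nt basal stem flanking the duplex, as
in real pre-miRNA precursors whose stems extend beyond the
miRNA:miRNA* duplex. The basal stem also makes the planted fold-back
the dominant structure under base-pair maximization; without it, random
±150 nt flanks out-pair a naked 19-bp duplex a few percent of the time.
Hairpins are planted on either strand, non-overlapping, with uniqueness
of every mature sequence verified genome-wide; decoys are rejected and
resampled if they contain a planted sequence.

Per-family expected counts are `depth × mirna_fraction × w_f / |f|`
(default fraction 0.25 of the library; relative family weights `w`
log-uniform over two decades, mirroring the orders-of-magnitude spread
of real family abundances), scaled by `2^lfc` in the stress condition
for families with a configured effect. Replicate counts are drawn
NB(μ, φ) with the same mean/dispersion parameterization the exact test
assumes (default φ = 0.1; φ = 0 gives Poisson), so dispersion recovery
is well-posed. Star reads are emitted for the first `n_star_hairpins`
hairpins by binomial thinning of the mature count at `star_fraction`
(default 0.1). The background fills each library to exactly its depth:
70% sampled from decoy features, 30% uniformly from the genome with the
hairpin spans excised (background represents degradation and siRNA-like
reads from non-miRNA loci; sampling them from inside a miRNA locus
would, by definition, be miRNA-locus signal). Everything is driven by
`(config, seed)`: identical inputs give byte-identical fixtures.

What the generator does **not** emulate: sequencing errors, adapter
contamination, quality-score structure, isomiR end variation, strand or
position coverage biases, true multi-locus miRNA families with
divergent members, and genome-scale reference complexity. Passing tests
therefore demonstrate correctness of the algorithms under the declared
generative model, not performance on real libraries — in particular,
annotation mismatch tolerance and repetitive-read handling face far
harder inputs in real genomes.

## Problem sizes used by the tests and the acceptance script

Fixtures are scaled so the full validation runs comfortably on a laptop
while keeping every estimate well-conditioned: the hairpin-recovery
fixture plants 10 hairpins (8 with sequenced stars) in a 100 kb genome
at depth 5×10⁴ per library — the genome size keeps background coverage
per position sparse (≈0.2 reads/position), which is the regime a real
genome's read density corresponds to, so that stray background reads do
not mimic star evidence at decoy loci; DE calibration uses 500 features
at 2 vs 2 replicates; folding- and scanner-oracle checks use 200 and 100
random instances; determinism runs the full pipeline twice on a
4-hairpin fixture. Unit tests use seeds fixed in the source; the
acceptance script derives all randomness from its `--seed` argument.

## Known limitations

- Base-pair maximization over-pairs random sequence relative to a
  thermodynamic model; the sequence-level register scoring in duplex
  evaluation compensates, but hairpin calls on real data should be
  confirmed with a free-energy folder.
- The common-dispersion exact test has no tagwise shrinkage, no TMM
  normalization and no GLM mode; it is intended for the simple
  two-group replicated design.
- The family-naming convention is heuristic; ids outside the
  `miR<number>` pattern need an explicit override map.
- Bulges larger than `max_bulge` are charged as mismatches rather than
  modeled as register shifts inside one duplex.
- The target scanner has no bulged or seed-weighted alignment mode and
  no expectation score.
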
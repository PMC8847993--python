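# Methods

## Screen model and hit-calling procedure

`slscreen` analyses pooled shRNA dropout screens with a two-genotype,
two-replicate design: knockout replicates KO1/KO2 and corrected controls
C1/C2. Clone abundance is read out by sequencing the integrated hairpin
barcode; a clone whose knockdown is lethal in the knockout genotype is
depleted there relative to the controls.

Per clone, the four cross-replicate ratios r₁₃, r₁₄, r₂₃, r₂₄ are
(KO replicate + pc)/(control replicate + pc) on (optionally normalized)
counts. The call hierarchy is deliberately rule-based, not model-based:

1. `depleted_all4`: all four ratios < 1 (consistent dropout, any size);
2. `fivefold_all4 = depleted`: all four ratios ≤ 1/5 (strong dropout in every
   pairwise comparison; `enriched` mirrors it at ≥ 5);
3. gene candidate: ≥ 2 depleted clones of which ≥ 1 is five-fold depleted —
   two independent hairpins guard against off-target single-hairpin effects,
   the five-fold clone guarantees at least one strong phenotype.

Five-fold **enriched** genes (protective knockdowns) are reported in a
separate table rather than mixed into the synthetic-lethality candidates,
because the candidate definition is directional: depletion in the knockout.

### Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| `pseudocount` | 1 | added to numerator and denominator; zero counts are certain in dropout screens and would otherwise produce undefined ratios. With `pseudocount=0`, clones with a zero among the four design counts are dropped with a logged tally. |
| `normalization` | `cpm` | counts-per-million per sample before ratios. Replicate sequencing-depth differences otherwise masquerade as biology; `raw` mode is provided for fidelity to raw copy numbers and for auditing. Column totals include controls. |
| `fold_threshold` | 5 | the five-fold rule; raising it can only remove flags (tested monotonicity). |
| `min_depleted`, `min_fivefold` | 2, 1 | the gene rule. |
| `min_count` | 10 reads | abundance floor: clones with all four raw counts below it are excluded from z standardization (their ratios are dominated by shot noise) but kept, flagged, in all tables — filtering is never silent. |
| `include_controls` | true | nontargeting controls participate in z standardization (they estimate the null location/scale) but never in gene calls or the enrichment universe. |

### z-scores

The literature describing this procedure fixes the comparison (deviation of
hairpin frequency in the knockout from its corrected counterpart) but not the
statistic. The convention implemented here — declared, configurable, and
logged — standardizes each clone's mean log₂ ratio x = ¼ Σ log₂ r across the
standardization set using the sample standard deviation, so mean(z) = 0 and
sd(z) = 1 exactly over that set. On the default simulated conditions this
puts ~99% of truly effective synthetic-lethal hairpins below z = −1.5 while
the bulk of the library sits near 0. No claim is made that any specific
published z value is reproduced, since the published convention is not fully
specified.

### Enrichment

Candidate genes are tested per gene set with the hypergeometric upper tail
P(X ≥ k), universe = the genes the library actually interrogates (a
kinome-only screen tested against a genome-wide background would grossly
inflate significance). Both the unadjusted p < α flag (the convention in the
screen literature, α = 0.01) and the Benjamini–Hochberg q < α flag are
emitted so the difference is visible. q is clipped from below at p to keep
the q ≥ p invariant under floating-point round-off. Network export writes
node/edge tables with Jaccard-weighted edges (≥ 0.25 by default) in the style
of enrichment maps; there is no GO DAG propagation or live web query — gene
sets are file inputs by design, for reproducibility.

## The simulator: what it emulates, and what it does not

The generator reproduces the *shape* of a kinome screen: 513 genes at 4–10
clones per gene plus 100 nontargeting controls by default; log-normal
(μ = 0, σ = 1) relative clone abundances (uneven pool representation under
single-integration, low-MOI transduction); expected counts depth × abundance;
negative-binomial sequencing noise via a Gamma–Poisson mixture with
var = m + φm², φ = 0.05 by default (a typical mild overdispersion for pooled
screens; φ = 0 degenerates to Poisson). Designated synthetic-lethal genes
have each clone effective with probability `penetrance` (0.8), resampled so
every designated gene keeps ≥ 1 effective clone; effective clones are
depleted `fold_depletion`-fold (default 10) in the KO samples only.
Optionally, genes can instead be enriched `fold_enrichment`-fold. FASTQ
emission places the barcode at a fixed offset, substitutes each base
independently with probability `error_rate` (1%), and writes 4-line
Sanger/Phred+33 records with constant quality so outputs are byte-identical
under a seed. An `exact_depth` multinomial mode fixes per-sample totals for
conservation tests. Default depth is 5×10⁶ expected reads/sample; bundled
presets and the acceptance script use 2×10⁵, which keeps per-clone means
near 75 reads — ample signal for a 10-fold dropout — while runs stay in
seconds.

Deliberately **not** modeled: PCR amplification bias and jackpotting,
transduction/MOI stochastics beyond the abundance prior, position- or
cycle-dependent quality profiles, adapter read-through, and hairpin-specific
knockdown efficacy beyond the Bernoulli penetrance. Passing benchmarks on
these simulations therefore demonstrates that the *procedure* is implemented
correctly and is well calibrated under clean overdispersed counts; they do
not certify performance on real screens, where off-target effects and
amplification artifacts add structured noise the generator omits.

Seeding: one master seed; each stage (library, counts, FASTQ, gene sets)
derives a child generator from `SeedSequence([seed, stage])`, so identical
configs reproduce every artifact bit for bit and stages can be re-run alone.

When a simulated pipeline run has no user GMT, gene sets are synthesized over
the simulated universe with a couple of sets loaded with the designated
synthetic-lethal genes, so the enrichment stage always runs against a known
signal; a user-supplied GMT takes precedence.

## Barcode counting

Reads are assigned to the clone with the unique minimal Hamming distance
within `max_mismatch` (default 0 — exact-match, the conventional vendor
behavior); distance ties are `ambiguous`, everything else `no_match`, and
per-sample tallies satisfy assigned + no_match + ambiguous = reads processed.
Exact matches are resolved through a dictionary; only imperfect reads fall
back to a vectorized distance scan, and the brute-force all-pairs scan in the
test suite fixes the contract. Duplicate barcodes shared by different clones
are legal in the library (vendor libraries contain them) but reads hitting
them are ambiguous. Reads shorter than offset + barcode length count as
no_match with a warning. An optional reverse-complement mode tries both
orientations and declares ambiguity if they tie on different clones. Base
qualities are ignored.

## Numerical and degenerate-input choices

- Ratios with `pseudocount > 0` are strictly positive; with `pseudocount=0`
  a zero KO count yields ratio 0 and mean log₂ ratio −∞, which is excluded
  from z standardization (non-finite values never enter the moment
  estimates).
- An all-zero sample column aborts with an error: it indicates a broken
  input, and normalization would divide by zero.
- z standardization requires ≥ 2 clones in the set and nonzero variance;
  a zero-variance screen is an error, not a silent z = 0.
- Gene tables are ordered by ascending best z with alphabetical tie-break;
  all floats are written with `%.6g`, making every TSV byte-stable.
- Hypergeometric bounds (max(0, n+K−N) ≤ k ≤ min(n, K)) are validated before
  calling the tail; violations are caller errors, not p = 0/1.

## Known limitations

- The gene rule interprets "five-fold difference" as the same
  all-four-comparisons criterion used for clone significance; a laxer
  reading (five-fold in any single comparison) would admit more candidates.
  The strict reading is internally consistent and is the one implemented.
- No replicate-variance moderation, rank aggregation, or Bayesian
  essentiality modeling: the package implements the classical ratio/five-fold
  procedure and benchmarks it honestly, rather than replacing it.
- Gene symbols are upper-cased verbatim; no alias resolution, so the gene
  universe is exactly the annotation file's.
- With only two replicates per genotype, the procedure has no within-genotype
  error estimate; the z-score is a library-wide standardization, not a
  per-clone test statistic.
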
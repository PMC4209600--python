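# Methods

## Scope and model of the data

`mirescape` analyses a two-condition overexpression screen with **one
RNA-seq library per condition** (a vector-control line and a
miRNA-overexpressing line). With no replicates, no sampling-based
differential test is attempted anywhere: expression changes are
effect-size classifications on RPKM fold changes, and shortening calls
are effect-size cutoffs on coverage ratios. Every threshold below is a
tunable parameter with the stated default.

## Seed-site model

Target motifs are derived from the mature miRNA (5′→3′, RNA alphabet,
length ≥ 8; `T` accepted and normalised to `U`):

* **7mer-m8** — reverse complement of miRNA positions 2–8 (1-based from
  the 5′ end), written mRNA-sense 5′→3′;
* **8mer** — the 7mer-m8 motif followed by `A` (the adenosine opposite
  miRNA position 1);
* **7mer-A1** — reverse complement of positions 2–7 followed by that `A`.

Scanning is exact string matching on the sense strand of the supplied
UTR sequence (`N` never matches); strand is resolved upstream, at UTR
extraction from genomic FASTA (minus-strand UTRs are
reverse-complemented at the reader boundary). Matches are reported
*maximal-type*: an 8mer match necessarily implies a 7mer-m8 match at
the same offset and a 7mer-A1 match one base downstream, and those two
implied matches are suppressed; all other matches are reported even
when they overlap. Per-gene tallies put 7mer-m8 and 7mer-A1 in a single
7mer column (a switch restricts the column to 7mer-m8 only, since
tabulations in the field sometimes mean only that class by "7mer").
Wobble (G:U) pairing, 6mer sites, and context/conservation scoring are
deliberately out of scope.

## Expression classification

RPKM = count ⁄ (exon length ⁄ 10³) ⁄ (mapped reads ⁄ 10⁶). Library
sizes default to the column sums of the counts table but should be
given explicitly when the table covers only a slice of the
transcriptome (column sums then misestimate sequencing depth). Fold
change is (RPKM_miR + ε) ⁄ (RPKM_vec + ε) with ε = 0 by default: a
pseudocount is opt-in so folds are never silently shifted. The scalar
operation raises on a zero denominator; at table level a gene absent
from the vector library gets fold `inf` (`nan` when absent from both)
— such genes sit below the read floor and are excluded anyway.

Class labels partition the gene universe:

| label | rule | boundary convention |
|---|---|---|
| `low_read_excluded` | raw counts < 10 in **both** conditions | strict |
| `repressed` | fold ≤ 0.5 | inclusive |
| `increased` | fold > 1.5 | strict |
| `unchanged` | otherwise | — |

The low-read filter is evaluated first for every gene by default
(`filter_scope="all"`, a symmetric rule); `"increased_only"` applies it
only to would-be increased genes, reproducing the screen workflow in
which low-read genes were dropped from the increased cohort only. The
fold histogram bins finite folds with half-open bins (right-inclusive
last bin, numpy convention).

## Shortening statistic

The published screens of this kind call 3′UTR shortening by eye in a
genome browser; this package defines the statistic explicitly, in the
DaPars tradition:

1. **Changepoint.** On the miRNA-condition track (the condition
   expected to shorten), minimise the two-segment piecewise-constant
   residual sum of squares of log₂(coverage + 1) over splits
   k ∈ [minseg, L − minseg]. The log transform stabilises the variance
   of deep tracks; segment means are reported on the raw scale. Ties
   break to the smallest k. A track whose splits all give equal RSS
   (relative spread ≤ 1e−9, e.g. constant coverage) is flagged *flat*
   and reported at k = minseg; flat fits never support a shortening
   call. `minseg` defaults to min(25 bp, L ⁄ 10). A raw-scale variant
   (`transform="raw"`) is available; its fitted breakpoint is exactly
   invariant to scaling the track by a positive constant.
2. **Distal usage.** DUI = (mean cov[k:] + ε) ⁄ (mean cov[:k] + ε)
   with ε = 0.5 reads guarding empty segments, computed for both
   conditions at the split fitted above (the question is asymmetric:
   does the miRNA line lose the distal UTR the vector line retains?).
3. **Call.** *shortened* ⇔ DUI_miR ⁄ DUI_vec ≤ τ (default 0.5) AND
   miRNA-track proximal mean ≥ 5 reads AND not flat. *seed-lost* ⇔
   shortened AND at least one seed site starts at or beyond k; the
   implication seed-lost ⇒ shortened holds on every output. A separate
   `lost_in_both` annotation marks transcripts whose **vector** track
   is itself distally dead (DUI_vec ≤ 0.1): the between-condition ratio
   is blind to loss present in both lines, so such transcripts are
   surfaced rather than called. Tracks shorter than 2·minseg or with
   mean coverage < 1 read/base fail QC and produce a no-call row.

Isoform-level escape is the expression share of isoforms whose 3′UTR
lacks the seed (undefined, and signalled, at zero total expression).
Multi-breakpoint segmentation and de novo polyadenylation-site
annotation are out of scope.

## Over-representation

For each query list, overlap with each gene set is tested with the
hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K, n) (SciPy's
survival function; the test suite checks it against exact rational
enumeration for all N ≤ 12). p-values are Benjamini–Hochberg adjusted
within each list; sets rank by ascending p, ties by descending overlap
then name. The universe defaults to genes with detectable expression
(count > 0 in either condition) in the screen's counts table,
overridable to the GMT union. Matching is case-insensitive symbol
equality; identifier aliasing is out of scope. Published pathway
rankings from proprietary web services are treated as qualitative
context only — their scoring is undocumented and not reproducible, so
this package substitutes the standard hypergeometric test and says so.

## Synthetic screens

The generator emits a complete input bundle (UTR FASTA, BED12,
per-condition counts TSV and bedGraph coverage, GMT, truth TSV,
metadata JSON) from one `numpy.random.Generator`; a fixed seed makes
every file byte-identical across runs.

* **Sequences.** Background DNA is rejection-sampled until motif-free,
  then motifs are planted at recorded offsets (8mer in the distal
  0.35–0.85 of the UTR, a 7mer proximally) and the sequence re-scanned
  until the scanner sees exactly the planted truth — so planted-site
  recovery is exact by construction, with no accidental sites.
* **Counts.** Negative binomial via the gamma–Poisson mixture;
  default dispersion 0.05 models burstiness of a single library per
  condition, base means log-normal (median 200, σ = 1). Planted folds:
  up ~ U(2, 5), down ~ U(0.1, 0.45), null = 1. Twenty genes are forced
  low-read (both means ≤ 3 reads, so both counts fall below the floor
  with probability ≥ 0.99; their planted fold is clipped to 2, still
  above the increased threshold).
* **Coverage.** Per-base Poisson at depth 30× scaled by the planted
  fold (clipped to [0.25, 4]); shortened genes — half of the
  up-regulated 8mer carriers — have the miRNA-condition rate divided by
  the step factor (default 8) beyond a breakpoint planted ≥ 10 bp
  proximal to the seed site, so every planted shortening also loses the
  seed. Coverage depth is deliberately decoupled from the count table's
  base means: it models UTR pile-up at a common working depth, not
  library-wide abundance.
* **Gene sets.** Twenty sets of 40 genes; one is drawn by weighted
  sampling without replacement with odds 9 for true up-regulated genes
  (odds 1 gives an exactly null set, used for type-I calibration), the
  rest uniformly.

Defaults were chosen once as a realistic desk-scale screen with effects
clear of the thresholds. What the generator does **not** emulate: GC or
mappability bias, positional coverage trends along transcripts,
multi-isoform count mixtures, replicate structure, gradual (multi-site)
APA shifts, and correlated gene–gene expression. Passing recovery tests
therefore demonstrates correctness of the detectors under the stated
generative model, not their power on real libraries with these
artefacts.

The **paper-mimic preset** reproduces a published screen's cohort
arithmetic: 30 increased 8mer targets (16 named cohort genes with their
published relative-expression values and shortening flags, 14 low-read
genes), plus repressed, 7mer-only and no-site background (130 genes
total). Counts are emitted as deterministic expectations so empirical
folds equal the published values, and nominal equal library sizes
(10⁶) are recorded in the metadata because the simulated genes are a
slice of a transcriptome, not whole libraries. The packaged reference
tables carry two internal inconsistencies of their source verbatim
(one gene marked shortened in one table and not the other; eleven "Yes"
rows where the narrative counts ten) — the fixtures surface these
rather than resolving them.

## Recovery experiments and problem sizes

The acceptance-style checks run at sizes chosen for a laptop-scale
test suite: 1,000 random sequences (≤ 500 nt) for scanner/brute-force
equivalence; 500 random tracks (≤ 200 bases) for changepoint/exhaustive-
RSS equivalence, where equivalence means the fitted split attains the
exhaustive RSS minimum within 1e−9 (exact ties are broken by float
noise in either direction); 200 transcripts for planted-APA recovery,
generated with a site in every transcript and half the up-regulated
genes shortened so both the planted and negative classes are well
populated while noise, depth and step factor stay at the defaults; 500
null simulations for type-I calibration of the gene-set test (the
discrete hypergeometric makes the test conservative, so the rejection
rate at α = 0.05 is expected somewhat below 0.05); and a 60-gene screen
run twice for byte-level determinism.

## Known limitations

* One library per condition: all calls are effect-size based;
  uncertainty is not quantified.
* The changepoint model fits exactly one breakpoint; tandem APA with
  several sites is reduced to its dominant step.
* The breakpoint is fitted on the miRNA-condition track only; events
  present only in the vector line appear as `lost_in_both` (via the
  absolute DUI cutoff) or are missed.
* RPKM is the only normalisation offered (matching the screens this
  pipeline targets); composition effects between conditions are
  handled by passing explicit library sizes, not by TMM-style factors.
* Gene identifiers are matched as case-insensitive symbols; no alias
  resolution.
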
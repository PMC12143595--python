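# Methods

This note documents the models, procedures and numerical choices behind
`pioneerkit`. It describes what each stage computes and under which
assumptions, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Problem setting

A pioneer transcription factor can bind nucleosome-occupied (closed)
chromatin and initiate its opening. The package dissects this activity at a
set of recurrent binding sites into independent layers:

1. **Accessibility transition** — is an accessibility (ATAC-type) peak
   present at the site before and/or after factor activation?
2. **Chromatin state** — which of four collapsed states (promoter,
   enhancer, transcription, quiescent) did the site occupy before
   activation?
3. **Transcription initiation** — does the site overlap a CAGE-detected TSS,
   and is that TSS induced upon activation?
4. **Response element (RE)** — does the site carry a canonical RE (two
   decameric half-sites without a spacer), a noncanonical RE (three
   quarter-sites, 1-bp-spaced half-sites, a single half-site), or none?

Around these classifications the package profiles nucleosome occupancy and
initiation density at RE centers, fits an occupancy-to-transcription
response curve, and links induced enhancer TSSs to distal target genes.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention); adjacency never
counts as overlap. A read's 5' end is `start` on the plus strand and
`end - 1` on the minus strand. Peak presence at a site means at least one
shared base. CTSS summit ties break to the genomic-leftmost position, which
makes summit calling deterministic under permutation of the input. The
200-bp upstream extension of TSS peaks before site overlap is strand-aware
(a minus-strand TSS extends to the genomic right); this is configurable.

Region counting assigns a read to *every* region it overlaps, so reads
spanning k regions contribute k incidences. CAGE counting uses single-base
5' positions and strand matching; the library orientation is a switch
(`cage_strandness`): `reverse` implements the reverse-stranded convention in
which a read is assigned to features on the opposite strand, `forward`
matches strands directly (the synthetic reads are emitted on the transcript
strand, so the pipeline default is `forward`), `none` ignores strand.

## Differential test

The differential stage is a deliberately simple negative-binomial Wald
test, not a reimplementation of a full RNA-seq differential framework (no
dispersion-trend fitting, no fold-change shrinkage priors, no outlier or
independent filtering):

* **Normalization** — median-of-ratios library-size factors, rescaled to
  geometric mean 1; total-count scaling is the logged fallback when no
  region has all-positive counts.
* **Effect size** — `log2FC = log2((m_t + c) / (m_c + c))` on normalized
  condition means, pseudocount `c = 0.5`.
* **Dispersion** — per-region method of moments on pooled within-condition
  variance of normalized counts (`Var = mu/f + alpha*mu^2`), floored at 0
  and shrunk toward the across-region median with weight `w = 0.5`.
* **Inference** — Wald statistic with the NB variance by the delta method;
  two-sided tails of a *t* reference with Satterthwaite-style effective
  degrees of freedom `df = (n_t + n_c - 2) / w^2`. The rationale: shrinking
  the dispersion toward a (nearly noise-free) across-region median with
  weight `w` scales the variance of the variance estimator by `w^2`, which
  inflates the effective degrees of freedom accordingly. With 4+4
  replicates and `w = 0.5` this gives df = 24; a plain normal tail is
  measurably anti-conservative at this sample size, and a raw t with df = 6
  overshoots in the other direction.
* **Multiplicity** — Benjamini–Hochberg step-up (via statsmodels).
  Classification uses strict inequalities: increased iff `log2FC > 1` and
  `FDR < 0.1`; decreased symmetrically; defaults configurable.

Calibration is verified by Monte Carlo: on null count matrices
(2000 regions, 4 vs 4, NB dispersion 0.05, depth 1e6) the raw-p rejection
rate at alpha = 0.05 averages ≈ 0.055 over 20 seeds, and the average
fraction of null regions flagged at q < 0.1 is far below 0.1. Effect
recovery is reported as the mean estimate across spiked regions
(true log2FC = 2): the per-region scatter is set by the NB dispersion
itself (SD ≈ 0.23 at dispersion 0.05), not by the estimator, so a
per-region guarantee tighter than that scatter would be a statement about
sampling noise rather than about the method.

## Occupancy-to-transcription sigmoid

The response of local initiation to factor occupancy is modeled as a
four-parameter logistic on log10 occupancy:

    y = a + (b - a) / (1 + exp(-(log10 x - x0) / k))

fit by least squares with multi-start initialization (x0 over the
{10, 25, 50, 75, 90}% quantiles of log10 x, k over {0.1, 0.3, 1}), keeping
the lowest-SSE solution and normalizing to k > 0. `x0` is the occupancy
threshold estimate (reported also as CPM, `10^x0`). The fit reports r² and
the two-sided Spearman correlation. Constant responses are flagged
degenerate; if no start converges, a straight-line fallback is returned and
flagged. The fit runs on all sites with a measured local initiation change
(≥ 5 pooled CAGE reads in the site window by default; configurable) — the
exact fitted subset is a genuinely open choice and is exposed in the
configuration rather than hard-coded.

## Nucleosome profiling

Mono-nucleosome-sized fragments (180–240 bp inclusive; boundaries exact)
build an occupancy track; each retained fragment contributes unit mass
spread uniformly over its span (midpoint placement is the configurable
alternative; uniform is smoother at moderate depth), scaled to counts per
million retained fragments. Tracks are averaged in ±500 bp windows anchored
at RE centers (minus-strand anchors mirrored; edge windows zero-padded and
counted).

The control→treated contrast yields two scores:

* **Eviction** — mean occupancy within ±73 bp (≈ half the DNA wrapped
  around one nucleosome) in control minus treated; positive = loss.
* **Shift** — the lag maximizing the overlap-normalized cross-correlation
  of the mean-centered flank segments (|offset| > 73), searched over
  ±100 bp, signed so that movement away from the anchor is positive and
  averaged over the two flanks. Overlap normalization removes the
  triangular bias of finite-window cross-correlation; zero-variance flanks
  are skipped and a fully flat profile yields an undefined (None) shift.

No background-normalization of the occupancy track against accessible-DNA
signal is attempted; CPM scaling plus the two-condition contrast is the
substitute, since the package's checks are recovery on generated data, not
equality with any external nucleosome-positioning tool.

## Initiation density around REs

For canonical RE centers only, the 5'-end (CTSS) coverage in a ±200 bp
window (401 positions; the window anchor is the RE center, configurable) is
extracted per region; regions with fewer than 5 total reads are dropped;
each surviving region's vector is divided by its own total; the mean across
regions is the density profile, computed per condition and per collapsed
chromatin state. Each profile sums to 1, is invariant to region order and
per-region read depth, and stratified profiles recombine (weighted by
region counts) to the pooled profile exactly.

Mode detection smooths the profile with a 5-bp moving average and ranks
local maxima (minimum separation 20 bp) by height. A coarse enrichment
histogram bins RE-to-CTSS offsets into ceil(401/19) = 22-bp windows (last
bin truncated); enrichment is observed bin fraction over the uniform
expectation, so the width-weighted mean enrichment is 1. This histogram is
a deliberate simplification of k-mer-based positional enrichment scanning —
sequence-level analysis is out of scope.

## Enhancer-gene linking

Interaction pairs are inputs. Links whose CAGE-peak summit lies closer than
2.5 kb to the annotated gene TSS are removed as promoter-proximal (summit
chosen as the anchor because it is single-base and deterministic);
cross-chromosome pairs count as distal. A candidate target gene has at
least one link whose peak is factor-bound and significantly induced
(log2FC > 1, FDR < 0.1) with the gene itself upregulated (log2FC > 0.5,
FDR < 0.05), all inequalities strict; genes are deduplicated, evidence
retained per link. Candidate sets are monotone in the thresholds.

## Synthetic-data generator

The generator produces the data structure the analysis assumes, with a
recorded ground truth, so every stage is testable without external data.
Reference conditions (defaults):

| parameter | default | rationale |
| --- | --- | --- |
| genome | 2 × 300 kb | large enough for ~1 kb site spacing at 500 sites |
| sites | 500 | desk-scale stand-in for the study's 7705 |
| RE class probs | 0.70 / 0.18 / 0.12 | matches the study's canonical (5388/7705) and annotated (6762/7705) fractions |
| state probs | 0.15 / 0.25 / 0.25 / 0.35 | regulatory-genome-like mix |
| occupancy | log-normal, median 10 CPM, sigma 1.2; ×1.8 at open sites | graded binding with open-site bias |
| constitutively open | baseline 0.27, state multipliers 2.0/1.6/0.5/0.35 | ~27% open, concentrated in promoters/enhancers |
| eviction (opening) | logistic in log10 occupancy, x0 = 1.6, k = 0.3 | ~20% of closed sites open on treatment, occupancy-gated |
| transcription induction | max log2FC 4 × logistic(x0 = 1.48, k = 0.25) | sigmoidal occupancy response, recoverable by the fit |
| TSS offsets | mixture at {0, +50} bp, sd 5, weights 0.5/0.5 | bimodal initiation at and ~50 bp from the RE |
| fragment classes | sub-nucleosomal < 120 bp; mono 180–240 bp | exact class boundaries used by the analysis |
| replicates | 4+4 accessibility/CAGE, 2+2 histone | the study's replication structure |
| noise | NB with variance mu + 0.05 mu²; uniform Poisson background 2e-4 /bp/library | replicate overdispersion; neutral background |
| depth | 1e5 events per library | desk-scale; per-site means rescaled to hit this total |

Open/closed ground truth is defined by the simulated nucleosome layout
(open sites have a depleted center with positioned flanking dyads at
roughly ±160 and ±340 bp; closed sites carry a nucleosome over the RE), not
by the downstream classifier's peak rule — classifier recovery is therefore
a genuine test (≈ 95% agreement at default depth). Gene-level differential
results are simulated directly: only the linking logic is in scope for
gene-side analysis, and wired genes' fold changes track their enhancer's
induction (attenuated, with noise) while clearing the candidate thresholds,
so noise-free recovery of the wired set is exact at the linking-module
level. A null mode forces every treatment effect to zero while keeping
replicate noise. A separate count-level generator emits region × sample NB
matrices directly for calibration and effect-recovery studies, where
fragment-level simulation would add nothing.

What the generator does **not** emulate: sequence (no FASTA, motifs or GC
effects), mapping bias, Tn5 insertion bias, chromosome-scale state
structure, peak-shape heterogeneity, or inter-site correlation. Passing
recovery tests therefore demonstrates the correctness of the analysis
logic under the assumed signal structure, not performance on real
sequencing data.

## Pipeline

Stages execute in dependency order (peaks → transitions/states →
differential → CTSS/TSS status → sigmoid → nucleosome → density → links →
report). One seed flows from the configuration into the generator; stage
outputs are plain text, JSON keys are sorted, and no timestamps enter the
summary, so identical configuration and seed reproduce byte-identical
summaries. The manifest records a configuration hash, the seed and package
versions. The threshold peak caller (positions ≥ min_height grouped, gaps
≤ 100 bp bridged, runs < 50 bp dropped; CAGE peaks per strand with
min_length 1 and merge distance 50 bp) exists so the synthetic path is
self-contained; peak calling on real data is out of scope.

Default problem sizes in the shipped tests and the acceptance script (500
sites, 1e5 events/library, 20 × 2000-region Monte Carlo) were chosen so a
full run completes in seconds on one core while keeping the Monte Carlo
bands tight.

## Known limitations

* The NB test's t-with-effective-df inference is an approximation
  calibrated at the default design (4+4); very unbalanced or very
  low-replicate designs may deviate.
* Eviction/shift scores are profile-level (per site group), not per-site;
  single-site nucleosome calling is explicitly out of scope.
* The occupancy values consumed by the sigmoid come from the site table
  (CPM from binding signal); the package does not process binding
  (ChIP-type) reads itself.
* putatively_closed sites (open in control, closed in treated) are retained
  as a label; interpretation (likely false-positive peak calls) is left to
  the report.
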
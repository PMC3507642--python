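# Methods

`cistromedose` implements a comparative, dose-resolved analysis of a
transcription factor's binding landscape (its *cistrome*) under
small-molecule antagonism, and the integration of binding impact with
differential expression into direct-target calls. This note records the
models, conventions and numerical choices, and what the synthetic
benchmark does and does not establish.

## Coordinates and overlap

All genomic coordinates are 0-based half-open (BED convention)
throughout; MACS-style 1-based closed tables are converted on read. Two
intervals overlap iff they share ≥ 1 bp; half-open adjacency is not an
overlap. Peak-to-gene association uses the **summit** (the base of
maximal tag enrichment), not the peak edges, with an inclusive distance
bound (default 25 kb) to the nearest TSS of each gene; strand plays no
role in the distance. An edge-based distance is available via
`map_to_tss(..., use_summit=False)`.

Annotation categories are assigned by summit position with precedence
promoter > exonic > intronic > intergenic; the promoter window defaults
to (−1000, +100) around the TSS in the direction of transcription.
Fold over-representation divides the observed category fraction by the
genome-wide base-pair fraction of the category under the same
precedence, computed from the supplied chromosome sizes and gene
models.

## Tag density and per-site signal

Tag tracks bin the genome into fixed-width bins (default 32 nt); each
tag is extended from its 5′ end in the 3′ direction to an assumed
fragment length (default 200 bp, configurable — sequencing libraries
are typically sheared to a few hundred bp but the exact extension is a
free parameter) and increments every bin it overlaps.

A site's signal is the **one-step Tukey biweight** of the bin values
overlapping the site by ≥ 1 bp: with m = median, s = MAD (unscaled),
u_i = (x_i − m)/(c·s + ε), weights w_i = (1 − u_i²)² for |u_i| < 1 and
0 otherwise, the estimate is Σw_i x_i / Σw_i. Constants follow the
established one-step biweight convention from microarray signal
summarization: c = 5, ε = 1e−4. When MAD = 0 only values equal to the
median retain weight, so a lone outlier bin among constant bins is
ignored entirely; the estimator reduces to the mean when all values lie
within one MAD band and is permutation-invariant.

Fold changes are reported on the signed-ratio scale: r = treated /
reference, reported as +r when r ≥ 1 and −1/r otherwise, so |value| ≥ 1
always. When either signal is exactly 0 a pseudocount of 0.5 is added
to both. Dose trends smooth the fold-change series (sites ordered by
descending score, ties by descending fold enrichment, residual ties by
coordinate) with a moving average (window 100) and fit a least-squares
line.

**Regime dependence of the trend.** The "weaker sites change more"
pattern — a positive Spearman correlation between strength rank and
smoothed |fold change| — holds while the antagonist dose is
non-saturating, i.e. while the strong end of the spectrum remains
bound. At a saturating dose nearly all sites are lost and |fold change|
then *grows* with site strength (a lost strong site falls further to
background), flipping the correlation sign. The trend checks therefore
apply to low/middle doses.

## High-confidence filtering and % impact

"Negative" peaks called with ChIP and control channels swapped carry no
biology and bound the technical noise. A peak is high-confidence when
its caller score **and** fold enrichment both pass cutoffs (defaults
500 and 20); in auto mode the cutoffs are the smallest round values
(next multiple of 10 for score, next integer for fold enrichment)
strictly exceeding every negative peak, so the filter is monotone and
excludes the negative set by construction.

The **% impact** of a dose is computed on differentially occupied
sites: differential = maximal-cistrome sites with no ≥ 1 bp counterpart
in the minimal cistrome; a differential site is lost when it has no
≥ 1 bp counterpart in the treated high-confidence cistrome; % impact =
100 · lost / differential. Matching is by overlap, not peak id, because
peak boundaries shift between independent calls. Treated = maximal
gives 0%, treated = minimal gives 100%, and the metric is monotone
along a nested dose series. A signal-ratio-based impact variant is
deliberately not the default: the metric counts occupancy, not
magnitude.

## Conservation

Conservation comes from a track of non-overlapping scored elements
(UCSC-style BED5; scores > 1 are divided by 1000). The value at a
position is the covering element's score, else 0 — a point lookup, not
a window average. Profiles sample offsets −10 kb … +10 kb every 100 bp
(201 points) from each summit and average over peaks. Binary
conserved/non-conserved status of the summit feeds a two-tailed Fisher
exact test for association with regulation mode.

## Motifs

Scanning is a plain log-odds scan in bits against a background (uniform
by default, or the scanned set's composition), both strands, N-windows
skipped. PWM columns are regularized with a 0.01 pseudocount at
construction. The default hit threshold is 60% of the matrix's maximal
achievable score — a documented relative cutoff chosen because
historical scanner-specific cutoff conventions are not reproducible; an
absolute-bits threshold is accepted everywhere. A matrix is palindromic
iff it equals its reverse complement elementwise (homodimer-binding
signature).

Specificity is a Z-score against 100 random sequence groups matched in
number, length and chromosome of origin: Z = (bound − mean)/sd of the
per-group counts of sequences containing ≥ 1 hit, deterministic given
the seed. Element-pair spacing is the middle-to-middle distance of
co-occurring hits within 10–50 bp, histogrammed with its mode reported.
Sequence extraction for external ab initio discovery (top sites by
strength, ≤ 500 bp centred on the summit) is provided; discovery itself
is out of scope.

## Expression integration

Differential-expression tables are consumed per probe (signed-ratio
fold change, d-score, q-value). A gene is significantly regulated when
any probe passes q < 0.05 and |FC| > 1.5; genes whose passing probes
disagree in direction are excluded. Direct **activation** targets are
genes with drug-impacted binding near the TSS whose expression falls
under antagonist; **repression** targets those whose expression rises.
"Impacted" means present in the untreated maximal high-confidence
cistrome but absent (no ≥ 1 bp overlap) from the treated cistrome at
the stated dose (default: highest). qPCR concordance is Pearson on raw
(untransformed) score/enrichment pairs — the raw scale reproduces the
packaged validation table's r = 0.87 (log scale gives 0.73); both
one- and two-sided tails are reported since published correlation
p-values are frequently one-sided.

## Signature enrichment

Enrichment of a target list in a signature is the upper hypergeometric
tail within a universe (default: all genes on the expression platform).
Multiple testing uses Storey q-values with fixed λ = 0.5,
π̂0 = min(1, mean(p > λ)/(1 − λ)); forcing π0 = 1 reproduces
Benjamini–Hochberg exactly, which the tests assert. The network export
keeps signatures with q < FDR as nodes (weight = signature size) and
weights edges by −log10 of the pairwise overlap tail, dropping p = 1
edges.

## Synthetic benchmark

The generator defines the study conditions; its defaults are fixed, not
tuned per run:

| parameter | default | rationale |
|---|---|---|
| genome | 4 × 2 Mb | large enough for matched background sampling and 25-kb TSS windows |
| n_sites | 2000 | affinities log-normal(μ=0.3, σ=0.6), a realistic spread of strong and marginal sites |
| dose series | maximal, 0.1/1/10 µM antagonist, minimal | occupancy thresholds at affinity quantiles 0, 0.30, 0.60, 0.85, 0.865 — the minimal condition retains ≈ 13.5% of sites and the highest dose drives binding essentially to the minimal level |
| occupancy_noise | 0.02 | per-site probability of violating the threshold rule |
| tag model | Poisson, background λ = 0.5/bin, + 8·affinity at occupied sites | enrichment proportional to affinity |
| peak scores | 500 + 550·(affinity − min), σ = 15, floor 500 | spans ≈ 500–3100, the regime of the packaged validation table |
| negatives | 300 peaks, scores < 450, FE < 18 | strictly below any real site, so auto-calibration is exact |
| expression | 40% of 3000 genes linked 1:1 to sites, TSS 2–20 kb away; 60% activation mode; true |FC| log-normal(ln 2.5, 0.3), p ∈ 10^−U(3,8); null |log FC| σ = 0.1, p uniform | coupling of binding loss to expression in both directions |
| conservation | width-300 elements, score 0.8, centred on occupied summits | summit-anchored profile with sharp decay |
| motifs | palindromic 15-bp inverted repeat (AGAACA-nnn-TGTTCT-like) at every summit, sharper with affinity; 7-bp forkhead-like partner at 15 bp middle-to-middle | palindrome, specificity and spacing statistics all exercised |

Randomness derives from one root seed via named CRC-based substreams,
so adding a condition never perturbs earlier draws; every emission is
bit-reproducible.

**What passing the benchmark shows — and does not.** Because emitted
peaks sit at fixed true positions and negatives are strictly separated,
impact recovery is exact up to the planted occupancy noise; on real
data, peak-boundary jitter, duplicate reads, mappability and
input-normalization artifacts (all out of scope) would add error the
benchmark cannot measure. Null expression is exactly uniform-p by
construction, so target precision near 100% reflects the generator's
clean null, not microarray reality. The benchmark validates the
*logic and statistics* of the pipeline, not instrument-level noise
robustness.

## Problem sizes and determinism

The default test-suite and acceptance runs use the full default
configuration (2000 sites, 3000 genes, 8 Mb genome) plus reduced
module-level fixtures (200 sites, 1 Mb); the motif Z-score subsamples
500 bound sequences for its matched-background comparison. Degenerate
inputs are defined errors: empty differential set (impact undefined),
empty group in a two-group test, < 3 pairs for a correlation, window
longer than the series, auto-calibration against an empty negative set.
Fully tied rank-sum comparisons return p = 1.
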
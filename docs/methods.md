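# Methods

## Scope and model of the data

`borderquant` re-implements the quantification layer of a SoxB1 /
neural-plate-border study as a tested package: image-based colocalization
calling, ChIP-peak-to-gene-cluster enrichment, composite-motif scanning, and
bench statistics. Raw data acquisition (imaging, sequencing, peak calling,
DESeq2 fits, k-means clustering) is out of scope; the pipeline consumes peak
intervals (BED), TSS annotations (GTF), cluster gene lists, DE tables and CT
/ densitometry tables, and a synthetic-data module generates all of these
with ground truth so every stage is verifiable offline.

## Image colocalization

**Segmentation.** The DAPI channel is binarized with Bernsen's local
threshold: per pixel, the min/max over a (2r+1)² edge-clamped window
(default radius 15 px); where local contrast ≥ 15 the pixel is foreground
iff its intensity ≥ the local mid-gray, otherwise the window is assigned by
comparing its mid-gray to the global mid-gray of the bit depth (128 for
8-bit data). Connected clusters of ≥ 20 foreground pixels
(8-connectivity) are nuclei. No watershed splitting is applied — the
procedure counts connected clusters, exactly as in the Fiji workflow it
reproduces — so touching nuclei merge; see the generator notes below.

**Channel positivity.** Signal channels are thresholded with the
Rényi-entropy method: for each order α ∈ {1 (Shannon limit), 0.5, 2} the
split maximizing the summed foreground + background Rényi entropies is
found by exhaustive scan over occupied-bin splits, and the three optima are
merged with the Sahoo weighting rule (the combination used by the common
"RenyiEntropy" auto-threshold). Foreground is strictly above the threshold.
The positivity rule per nucleus is not specified by the original procedure;
we call a nucleus channel-positive when ≥ 10% of its pixels exceed the
channel threshold (`pos_frac`, configurable) — robust to single noisy
pixels while detecting partial nuclear signal.

**Regions and the statistic.** Region geometry is likewise unspecified in
the original procedure; we define a region as a uniformly drawn seed
nucleus plus its 49 nearest neighbours by centroid distance (ties broken by
lower nucleus id), deterministic given the seed; regions may overlap.
Per region the statistic is Sox3&pax3⁺⁺ / total pax3⁺ (NA when the region
has no pax3⁺ nucleus, excluded from stage means with a warning). The
default batch layout is 3 replicates × 2 explants × 3 regions = 18 regions
per stage. Stage summaries report means, quartiles and Tukey-fence
outliers (beyond 1.5×IQR from the quartiles). Thresholds are computed
per image, not per batch.

## Synthetic explants

The generator paints nuclei as filled discs (radius ~ N(6, 0.8²) px,
clipped ≥ 3 px so every disc exceeds the 20-px rule) at signal level 180
over background 25, with additive Gaussian noise (default sd 2) and latent
per-nucleus labels: pax3⁺ with probability `frac_pax3` (default 0.5);
pax3⁺ nuclei are Sox3⁺ with probability `frac_double_given_pax3` — the
ground-truth colocalization — and pax3⁻ nuclei with probability
`frac_sox3_only` (default 0.3). The `fig1c` profile fixes
`frac_double_given_pax3` per stage at 1.00 / 0.79 / 0.69 / 0.34 / 0.14
(stages 10.5 → 15).

Two generator choices matter and are deliberate:

* **Nuclei are non-overlapping by default** (centres ≥ r₁+r₂+2 px apart).
  A component-labelling pipeline without watershed cannot split touching
  nuclei, and merged pairs bias the double-positive fraction upward (a
  pax3⁺Sox3⁻ nucleus merged with any Sox3⁺ neighbour is miscalled
  double-positive). The default therefore emulates a well-spread monolayer
  in which nuclei are individually resolvable; `max_overlap_frac` can be
  raised to probe the pipeline's behaviour under crowding, where recovery
  degrades as expected.
* **Noise sd defaults to 2 intensity units.** Bernsen's low-contrast branch
  only suppresses background where the local intensity range stays below
  the contrast threshold (15); Gaussian noise with sd ≳ 2.3 makes the
  31×31-window range exceed 15, the local mid-gray adapts to the noise, and
  the background dissolves into near-percolating speckle that bridges
  nuclei. Confocal maximum-intensity projections are in practice low-noise
  relative to an 8-bit dynamic range; the default keeps the generator
  inside the regime where the published contrast default is meaningful.

What passing recovery tests shows: the pipeline's thresholding, component
and region logic is unbiased on resolvable, uniformly stained nuclei. What
it does not show: robustness to out-of-focus light, intensity gradients,
chromatin texture, or densely packed tissue — none of which the generator
models.

## Genome fixtures

TSSs are placed on a jittered grid (spacing 10 kb, jitter ≤ spacing/8, so
adjacent TSSs are ≥ 7.5 kb apart) across 4 chromosomes, strands random.
A peak "targeting" a gene is a 300-bp interval whose midpoint lies within
spacing/4 of that gene's TSS — geometrically guaranteed to be nearest to
it. Fixtures therefore hit requested association counts exactly, and the
generator verifies this by running the pipeline's own `nearest_tss` and
retrying on violation (the generator/pipeline closure property).

Profiles package the study conditions: `fig4` (5300 peaks, 596 with nearest
TSS in the 2114-gene border cluster = 11%), `fig4e` (gene-wise: 400 of 2114
border genes peaked = 19%, 10% NC, 8% blastula, 4% C10), and `fig6` (two
peak sets; 3500 of the 5300 border-set peaks = 66% overlap the second,
blastula-like set, which has 8000 peaks — scaled down from the ~10× larger
blastula peak compendium, whose absolute size depends on external raw
data). Counts the source figures do not print (non-border peak-wise counts,
filler background) are fixed once: non-border peak counts consistent with
the printed gene-wise coverages, and a 45 000-gene filler background
matching an allotetraploid annotation's scale. Published odds ratios are
*not* reproduction targets — they depend on an unprinted background
universe — but on these fixtures the border cluster is the only enriched
one, as in the source analysis.

## Enrichment statistics

The 2×2 table is gene-centric over a stated universe (rows: in cluster /
not; columns: ≥ 1 associated peak / not). Fisher's two-sided exact p sums
hypergeometric probabilities of all same-margin tables no more probable
than the observed one (SciPy's implementation; verified in tests against
full enumeration for all small tables). OR = (a·d)/(b·c) with the
Haldane–Anscombe +0.5 correction when a cell is zero (explicit ∞ when
disabled) and Woolf CIs exp(ln OR ± 1.96·√(Σ1/cell)). Peak-wise
percentages (share of all peaks, unassigned included in the denominator)
are reported descriptively alongside, as in the source figures.
Benjamini–Hochberg adjustment is available but off by default (the source
analysis reports raw p across its four clusters).

DE filtering uses strict inequalities — padj < 0.05 AND signed
log2FC > 1.5 (an `absolute` switch exists) — adopting the stricter of the
two conventions that appear in the source (its methods say ≤, its results
use <); the boundary is unit-tested and the cutoff configurable.

## Motif scanning

PWMs are L×4 log2-odds matrices: log2(((count + pc)/(total + 4pc))/bg),
pseudocount 0.25, uniform background by default. IUPAC consensus strings
expand to uniform probability over each letter's base set (100
pseudo-observations per column), so an `N` column scores 0 bits. The
default composite Oct4-Sox2 element is `CTTTGTTATGCAAAT`; any count matrix
replaces it.

Scanning slides both strands; `N` bases contribute 0 bits, keeping offsets
aligned. Significance uses the exact distribution of the score of a random
background L-mer, computed by dynamic programming over an integer grid
(granularity 10⁻³ bits). Scores are graded *on the same grid* (per-cell
rounding, then summation): rounding the float sum instead can disagree with
the DP by a grid step or two, which at sparse score levels (a single
mismatch in a 15-mer costs ~8.7 bits) would shift realized false-positive
rates by an order of magnitude. A p ≤ 10⁻⁴ scan threshold (default)
therefore realizes a per-window rate at or below 10⁻⁴ exactly. The
reverse-strand scan reuses the forward distribution, exact for
complement-symmetric backgrounds (the default uniform one included).

Incidence is the fraction of sequences with ≥ 1 hit, with a Wilson binomial
CI; at the default threshold on 200-bp sequences the union-bound
false-positive contribution is ≤ 2·186·10⁻⁴ ≈ 3.7% per sequence and
realizes near 0.5%, so implanted-consensus incidence tracks the implant
rate closely. TSS-relative hit positions are peak_start + offset − TSS for
+ strand genes (mirrored for − strand, upstream negative either way).

## Bench statistics

ΔΔCT assumes amplification efficiency 2.0 (no efficiency correction):
ΔCT = CT_target − CT_ref per biological replicate, ΔΔCT subtracts the
control-condition mean ΔCT, fold = 2^(−ΔΔCT); the reported sd is that of
per-replicate fold changes (matching "error bars = sd of three biological
replicates"). Densitometry lanes are normalized as signal/loading-control,
scaled by the mean baseline-stage ratio; percent decrease
= 100·(1 − normalized mean), with the signed change also reported. The
`fig1d` profile fixes true normalized ratios 1.0 / 1.25 / 0.55 / 0.2
(stages 9 → 15), i.e. an 80% decrease by stage 15. t-tests are two-tailed
equal-variance Student by default (the source names only "two-tailed
t-tests"); Welch via `equal_var=False`. Zero pooled variance returns p = 1
for equal means and p → 0 with a warning otherwise.

## Numerical and design choices

* Peak reference point: summit when present, else midpoint
  floor((start+end)/2); distance is point-to-point (midpoint ↔ TSS), signed
  TSS − midpoint with the sign flipped for − strand genes; |distance| ties
  break to the lexicographically smaller gene id.
* Coordinates are 0-based half-open internally; GTF (1-based inclusive)
  converts on read with TSS = start−1 (+) or end−1 (−).
* Unassignable peaks (gene-less chromosome) are retained with a null gene so
  peak denominators are preserved.
* Histogram thresholds use 256 bins over the full bit-depth range;
  degenerate single-bin histograms return that bin with a zero-foreground
  warning.
* All generators and pipeline stages are pure functions of (params, seed);
  preset runs write a manifest with sha256 content hashes and re-running an
  identical config reproduces identical bytes.

## Problem sizes

Default test and reproduction runs use desk-scale sizes chosen to exercise
every code path at full fidelity: 512×512 explants with 300 nuclei
(6 per stage), 5300-peak / ~50 000-gene genome fixtures, 1000 × 200-bp
sequence sets, and 1000-fixture null calibrations. The interval and
scanning code paths are vectorized (sorted sweeps, windowed numpy sums) and
assign 10⁵ peaks against 10⁴ TSSs in seconds.

## Known limitations

* No watershed or 3D segmentation; crowded or overlapping nuclei merge.
* No bleed-through, PSF or illumination-gradient modelling in the generator.
* Enrichment ORs on fixtures depend on the chosen background universe;
  only count-derived percentages are construction-exact.
* The reverse-strand p-value reuses the forward-strand distribution, exact
  only for complement-symmetric backgrounds.
* ΔΔCT assumes perfect doubling per cycle; no melt-curve or efficiency
  modelling.
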
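# Methods

This note documents the models and procedures implemented in `neuraging`,
the default parameters and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions and known
limitations a user should be aware of.

## Statistical primitives

**Welch's t-test.** Implemented from the definition with n−1 sample
variances and the Welch–Satterthwaite degrees-of-freedom approximation;
two-sided p from the t distribution. A vectorized row-wise variant
(`welch_t_test_rows`) applies the identical formulae across many
independent comparisons at once and is what the per-gene/per-event
pipelines use; the test suite verifies exact agreement with the scalar
path and with an independent reference implementation to |Δp| < 10⁻¹⁰.

Degenerate inputs follow documented conventions rather than silently
propagating NaNs: two constant, equal samples are an error in the scalar
API (no statistic exists) and p = 1 in the screening pipelines (identical
replicates carry no evidence); two constant, unequal samples give p = 0
with a degeneracy flag (an infinitely confident shift under the model,
which in practice marks noiseless synthetic data).

A property worth knowing: the *true* size of Welch's test at very small n
is below nominal — about 0.034 at n = 3 per group and 0.045 at n = 5
(normal data, α = 0.05). This is a finite-sample property of the
Satterthwaite approximation, not of this implementation; calibration
checks in the test suite therefore run at n = 5, and per-gene screens at
n = 3 should be read as conservative.

**Grubbs outlier filtering.** Two-sided, iterative: while
G = max|xᵢ−x̄|/s exceeds the critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t = t(1−α/2n, n−2), the most extreme
point is removed; iteration stops below n = 3 or at zero spread (a
constant sample has no outliers by convention). Iterative-until-
nonsignificant was chosen over single-pass because replicate sets may
contain more than one artifact; α defaults to 0.05 per condition per
metric.

**Likelihood-ratio (G) test, 2×2.** G = 2·Σ O ln(O/E) on the uncorrected
table with margin-derived expected counts and 0·ln 0 ≡ 0; p from χ²(1).
The odds ratio uses the Haldane–Anscombe correction (add 0.5 to every
cell) whenever any cell is zero, so it is always finite. A zero row or
column margin makes G undefined: the result is flagged degenerate with
p = 1 rather than raising, because margin collapse is a data property
(e.g. no bound exon called in a direction), not a caller error.

**Multiple testing.** Benjamini–Hochberg everywhere a q-value is needed
(delegated to statsmodels). BH controls the *expected* false-discovery
proportion; see Limitations for what that implies for per-seed behavior
of the locus map.

## Imaging quantification

Inputs are two-channel 2-D frames: channel 0 a DNA stain, channel 1 the
immunostained protein.

**Nuclear segmentation.** Gaussian smoothing (σ = 2 px), Otsu threshold,
hole filling, connected components, discard below 100 px², relabel. The
nuclear channel in both real and synthetic data is high-contrast, so a
global threshold suffices.

**Nuclear fraction.** Background is the median (configurable percentile)
of protein intensity outside the cell footprint, subtracted with clamping
at zero. The footprint is the union of the protein channel's Otsu mask
and the 10-px-dilated nuclei — the denominator is intensity within cells,
not the whole frame, so the measurement does not depend on how much empty
field a frame contains. Per-image fraction = Σ(protein in nuclei) /
Σ(protein in footprint); per-cell fractions use nucleus-seeded Voronoi
territories (nearest-nucleus assignment via a distance transform)
restricted to the footprint, because the assays define "per cell" without
a cytoplasmic marker for true cell segmentation. Both per-image and
per-cell values are reported. If the footprint carries no signal after
background subtraction the fraction is defined as 0 and flagged.

**Granule detection.** DoG band-pass (σ_small = 2.5 px, σ_large = 5 px by
default, matched to the granule scale), negative response clamped to
zero, Otsu threshold on the positive response, components below 20 px²
discarded. The Otsu threshold is floored at 5× the robust noise scale of
the DoG response (1.4826×MAD of the unclipped response): Otsu always
splits a histogram, so without the floor a featureless noise frame would
yield hundreds of spurious blobs. All thresholds were calibrated once on
the synthetic generator at its default signal-to-noise and frozen; they
are exposed in the API and CLI.

**Shape scores.** Circularity 4πA/P², roundness 4A/(π·major²), axes from
normalized second central moments. The perimeter estimator matters at
pixel scale and is therefore documented: P is the length of the
marching-squares boundary polygon after a 3-point circular moving
average. The raw 0.5-level contour overestimates smooth boundaries
(staircase bias: a digital disk scores ≈ 0.88); the light smoothing
brings a ≥ 20-px disk to 0.97 and a 24-px square to 0.82 against the
analytic π/4 ≈ 0.785, both within ±0.05. (The Crofton estimator was
rejected: it underestimates axis-aligned square perimeters by ~6%,
pushing the square's circularity to 0.90.)

**Condition comparison.** Per metric (nuclear fraction, granule count,
mean circularity, mean roundness): Grubbs filter each condition
independently at α = 0.05, then Welch on the survivors; removed indices
are reported.

## CLIP window annotation

Coordinates are 0-based, half-open and stranded throughout; GTF input
(1-based inclusive) is converted on ingestion. A window's element label
is the element with maximal base-pair overlap among same-strand
transcripts, with the fixed tie-break CDS > 3′UTR > 5′UTR >
noncoding_exon > intron and `intergenic` for zero overlap. Strand
matching is required because eCLIP libraries are strand-specific.
Element fractions are exact rationals over window counts (they sum to 1
identically). Window sharing between two condition sets uses a
reciprocal-style criterion: a window is shared when some same-strand
window on the other side covers at least `min_overlap_frac` (default
0.5) of the shorter of the two windows.

## Binding–splicing odds-ratio map

Each skipped-exon event contributes five loci: the exon body, the
splice-site-proximal `proximal_width_nt` (default 250 nt, truncated to
the intron) of each flanking intron, and the remaining distal intron
segments (possibly empty). Orientation is transcription-aware: on the
minus strand the genomically left intron is the downstream one, and the
test suite checks exact bin mirroring under coordinate reflection.

Differential inclusion calls: per event, Welch on PSI replicates
(condition B vs A), BH across events, then call `included_up` /
`excluded_up` when q ≤ 0.05 and |ΔPSI| ≥ 0.1 with the sign giving the
direction (an exactly zero ΔPSI is always `unchanged`). Binding is
defined as ≥ 1 nt overlap of a same-strand window with the locus
interval — windows are already enrichment-filtered upstream, and a
fractional threshold would penalize short bins.

Per locus, the 2×2 table {bound, unbound} × {called in direction, not} is
tested with the G test; q across the five loci by BH. The unit of
analysis is the event (exon), not the gene.

## Ribo-seq translation efficiency

P-site = 5′ end + 12 nt for 28–29 nt footprints, + 13 nt for 30–33 nt.
Reads of any other length (including 34 nt, which occurs in real
libraries) carry no offset rule and are discarded and counted — guessing
an offset would corrupt the P-site statistics. Reads are in transcript
coordinates (5′→3′), so the offset is always additive. A P-site counts
toward a gene only when it falls inside the CDS; out-of-CDS and
unknown-transcript P-sites are tallied. Count conservation
(assigned-in-CDS + outside + discarded = total) is asserted in tests.

TE = ((RPF + pc)/RPF library size) / ((RNA + pc)/RNA library size) with
pseudocount 0.5 and library size the column sum; differential TE is Welch
on log2 TE replicates with BH across genes. TE is library-normalized, so
it is *compositional*: if a noticeable fraction of the library shifts,
null genes move opposite the shifted set (a 2× gene that is 18% of a
library appears at log2 ΔTE ≈ 0.86, with null genes at ≈ −0.14). The
generators and tests therefore plant small subsets when absolute recovery
is asserted; users comparing conditions with global TE shifts should
interpret ΔTE as relative to the library.

## Protein/transcript integration

Per-gene log2 fold changes and Welch p (on log2 abundances), BH q.
Quadrants: `high_protein_normal_rna` requires protein q ≤ 0.05, protein
log2FC ≥ 1 and |RNA log2FC| ≤ 0.5 — "normal transcript" is geometric
(|log2FC| small) regardless of RNA significance, because flat transcripts
with tight replicates would otherwise be excluded for the wrong reason.
Mirrored and concordant labels partition the rest. The RBP-set test is a
Welch comparison of protein log2FC between flagged and unflagged genes,
reporting mean and median shifts; RBP membership is a user-supplied gene
list (the package does not bundle any published RBP catalogue; the
generators emit a synthetic flag).

## Synthetic-data generators

All generators are pure functions of their parameters and a seed
(bit-identical reruns); per-entity substreams are spawned from the seed
so enlarging a dataset never perturbs earlier entities. Every writer has
a documented plain-text (or TIFF) format and a YAML parameter manifest.

**Images.** Cells are a nucleus ellipse (radius ≈ 16 px) inside a soma
ellipse (+9 px rim) — the thin cytoplasmic rim of a neuronal soma in a
single confocal slice. The DNA channel is flat within nuclei. The protein
channel splits a per-cell budget (4×10⁵ counts) between nucleus and
cytoplasm so the in-soma nuclear share equals `nuclear_fraction_true`
exactly in expectation: the diffuse budgets are debited by the
actually-rendered focus mass inside the nucleus and the rest of the soma,
so focus tails crossing compartment boundaries do not bias the truth.
Foci are anisotropic Gaussians (σ = 2.5 px, amplitude 700 over a
background of 100 counts, elongation = major/minor σ ratio with the
product preserved) planted in the cytoplasm outside a 2-px dilation of
the nucleus, at least one major-axis σ inside the soma edge, and at least
5 major-axis σ apart so the planted truth is unambiguous. Poisson shot
noise is applied to signal + background, then Gaussian read noise
(σ = 3). Defaults give focus peak SNR ≈ 15 and were frozen after a single
calibration of the detector against them. Not emulated: cell-to-cell
contact, 3-D structure, chromatic shift, uneven illumination,
photobleaching — so passing tests demonstrate correctness of the
measurement pipeline, not robustness to those artifacts.

**Gene models.** Non-overlapping transcripts on one synthetic
chromosome, alternating strands; exons 150–400 nt, introns 600–2000 nt
(long enough that distal locus bins are non-empty), UTRs inside the
terminal exons, CDS spanning every exon boundary.

**Binding windows.** Element class per window drawn with probability
proportional to the configured weights; the window is placed entirely
inside one element instance, so truth labels are exact and
fully-contained recovery must be 100%.

**Skipped-exon datasets.** Each event anchors its own internal exon
(strided so events never share an intron — a window for one event cannot
contaminate another's binding vector). Binding per locus is
Bernoulli(0.3); the probability of differential inclusion is set on the
odds scale, odds = odds₀·Π locus_odds[b]^bound(b) with baseline rate 0.2,
so with a single non-null locus the marginal odds ratio equals the
planted value exactly (with several non-null loci, odds-ratio
non-collapsibility makes marginal and conditional ratios differ — the
standard grid checks plant one locus at a time). Differential events get
ΔPSI = +0.4; replicates are condition means + N(0, 0.05) truncated to
[0,1]. The 0.4 effect is a typical strong cassette-exon shift and makes
planted events reliably separable from replicate noise at n = 3 (Welch
power ≈ 0.95 at the BH-effective threshold; at ΔPSI = 0.3 the small-n
power ceiling is ≈ 0.82 regardless of implementation). Truncation to
[0,1] slightly biases means for events near the boundaries; bases are
drawn in [0.2, 0.5] so the planted contrast is unaffected.

**Expression pairs.** Log-normal replicate abundances around per-gene
baselines; a designated subset gets protein log2FC = +1.5 with flat RNA,
a disjoint RBP-flagged subset gets the configured protein shift
(default −1.0, emulating depletion). With both subsets planted, the
non-RBP background mean includes the +1.5 subset, so the RBP-vs-rest
contrast includes that offset by construction; recovery tests for the
shift itself use a pure null background.

**Footprints.** True P-sites uniform in the CDS; the 5′ end is placed at
P-site − offset using the length drawn from the configured distribution
(lengths without an offset rule use the 30–33 convention for placement
only — the analysis side discards them, which tests exercise). RPF depth
∝ abundance × TE, RNA counts ∝ abundance, both Poisson. A count-level
companion (`simulate_te_counts`) supports large calibration studies
without read placement.

## Demonstration run

`neuraging demo` generates an aged-vs-young contrast at defaults chosen
to reflect the phenotypes the pipeline measures: aged nuclear fraction
0.3 vs young 0.5; aged foci elongation 3 vs round; aged binding windows
3′UTR-shifted (weights 0.25/0.25/0.50 intron/CDS/3′UTR) vs intron-rich
young (0.60/0.25/0.15); one planted locus at odds ratio 4; 5% of genes at
2× TE; a 10% high-protein/normal-RNA subset (replicate log2 noise 0.25,
n = 4 — typical DIA-proteomics replicate scatter, at which per-gene Welch
calls carry FDR power) and a 20% RBP subset at −1.0. Stages are isolated:
a validation failure in one is reported and the others complete. The full
run takes a few seconds; all problem sizes are configurable.

## Known limitations

- The locus map's BH q-values control expected FDR across the five bins,
  not familywise error: with one overwhelming true discovery, a null bin
  is co-rejected in ≈ 8% of datasets (a null p ≤ 2/5·0.05 suffices).
  "Exactly one discovery" therefore holds in ≈ 92% of seeds, not more —
  an inherent property of BH at q ≤ 0.05, not a defect of the test
  statistic.
- Welch at n = 3 is conservative (true size ≈ 0.034 at nominal 0.05);
  per-gene screens at triplicate scale under-reject accordingly.
- TE is compositional (see above); absolute ΔTE is only interpretable
  when the shifted fraction of the library is small.
- Image measurements are validated against the generator's geometry;
  heavily confluent fields, out-of-focus frames or saturated pixels are
  out of scope.
- The circularity/roundness values depend on the documented perimeter
  and axis estimators; comparing against other software requires matching
  estimators, not just formulas.
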
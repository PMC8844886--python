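# Methods

This note documents the models and procedures implemented in `ribofish`,
the parameter choices made where the design was genuinely open, what the
synthetic data do and do not emulate, and the package's known limitations.

## Image model and puncta quantification

**Scene model.** A synthetic field is a two-channel (C, Z, Y, X) stack with
voxel calibration (default 0.25 × 0.2 × 0.2 μm in z, y, x — confocal-like
sampling with a 16-slice, 4 μm depth). The marker (IF) channel renders a
straight tube of radius 1.5 μm — an idealized dendrite — at a constant
intensity over background; the FISH channel renders each mRNA punctum as an
isotropic 3D Gaussian of σ = 0.2 μm (a 0.69 μm diffraction-limited diameter
at the 2√3·σ blob-diameter convention). Noise is additive Gaussian in both
channels; the peak blob amplitude is SNR × background SD (default SNR 5,
background 100 ± 20). Puncta are planted by dart-throwing with a 0.9 μm
minimum separation; "inside" puncta sit within 0.6 of the tube radius from
its axis and "outside" puncta at least 1 μm beyond it, so the planted
inside/outside label is unambiguous under the co-localization rule and the
ground-truth flag always equals mask membership of the centroid voxel.

**Marker mask.** Threshold = mean + k·SD of the channel over all voxels of
the field (default k = 2), mask = voxels strictly above. Computing the
statistics over the whole field (rather than a segmented background) is the
simplest defensible choice when no background region is annotated; on the
synthetic tube it recovers ≥ 95 % of tube voxels at ≤ 1 % background
false positives. A more robust percentile-based variant can be substituted
by passing a precomputed threshold.

**Spot detection.** Scale-normalized Laplacian of Gaussian. For blob
diameter d the matched scale is σ = d/(2√3) (the 3D optimum for a Gaussian
blob); three log-spaced scales span the 0.5–1.0 μm diameter range. Second
derivatives are taken per axis with explicitly zero-sum
second-derivative-of-Gaussian kernels (scipy's truncated derivative kernels
are not zero-sum at sub-voxel σ, which would give a constant image a
non-zero response) and converted to physical units through the voxel
calibration, so anisotropic sampling is handled exactly. Candidates are
spatial local maxima per scale; across scales, a detection within one blob
radius of a stronger one is suppressed. The diameter is refined by
parabolic interpolation of the response across log-scale.

**Detection threshold.** With no user threshold the detector calibrates
itself against a Gaussian white-noise null: the image's robust noise SD
(normalized MAD) times the L2 norm of the response filter gives the
response SD of pure noise, and the threshold is the 99.9 % quantile of the
*maximum* noise response over the image (independent-voxel tail
approximation). Controlling the maximum rather than the per-voxel tail is
essential: a per-voxel 99.9 % cut on a ~2.4-million-voxel stack would admit
roughly two thousand false maxima per image. Contrast ((peak − shell
mean)/shell mean) and total-intensity filters are available on top but are
off by default.

**Co-localization.** The neighborhood of a punctum is the 3×3×3 voxel cube
around its rounded centroid minus the four corners of the central z-slice —
23 voxels. (A cube has eight 3D corners; only the four-in-plane-corner
reading yields the canonical count of 23, and the excluded-offset set is a
single module constant should the other reading ever be wanted.) Rounding
is half-up per axis. A punctum is co-localized iff strictly more than 60 %
of its in-bounds neighborhood voxels lie in the mask: 14/23 passes, 13/23
fails. Density is co-localized puncta divided by mask volume (voxel count ×
voxel volume). Dendrite densities use the same rule against the trace's 3D
fill and divide by the trace's path length; per-soma counts use the 2D
analogue (3×3 minus four corners = 5 pixels) on maximum projections, with
ties between overlapping ROIs going to the larger overlap, then the lower
label.

**Tagged-ribosome IF statistic.** For projection images the reported value
is mean(HA | marker-positive pixels) − mean(HA | all pixels). This sign
convention makes a genotype with tagged ribosomes in marker-positive
neurites score positive and a tag-free control score ≈ 0, which is the
interpretable direction; the opposite subtraction order would merely flip
every sign.

## UMI counting

Reads carry a well barcode and UMI in read 1 and a gene assignment (from a
tag table or read-2 header); alignment is out of scope. Poly(A) trimming
removes the longest 3′ suffix that starts with an A, is at least 7 bases,
and contains at most one non-A per 10 bases — the tolerance mirrors common
trimmer behavior. Barcode correction accepts exact whitelist matches and
unique Hamming-distance-1 neighbors ('N' mismatches everything; more than
one 'N' rejects; two distance-1 neighbors reject as ambiguous, tallied
separately from distant rejects). The default 96-well whitelist has
pairwise distance ≥ 3, making single-error correction provably unambiguous.
Collapse proceeds in two steps: exact (well, UMI, gene) deduplication, then
merging of UMIs within Hamming distance 1 inside each (well, gene) group.
The default merge takes connected components of the distance-1 graph
(representative = highest read count, ties lexicographic); the directional
count-ratio rule (merge b into a iff count(a) ≥ 2·count(b) − 1) is
available by option. Components are found via wildcard indexing
(O(n·L) neighbor lookup), and the test suite proves equality with an O(n²)
pairwise-Hamming oracle on hundreds of random groups.

Two consequences of the components rule are worth knowing. First, it is
lossless in the error-free limit only if distinct true molecules carry UMIs
at distance ≥ 2; the read simulator therefore draws true UMIs per
(well, gene) with that separation, which is the realistic regime when tag
diversity (4^8 = 65,536) vastly exceeds per-gene molecule counts. Second,
adding a novel UMI can *merge* two previously separate components (a
bridge), so molecule counts are not monotone in reads in general; duplicate
reads of existing UMIs never change the grouping.

## Enrichment model

Counts are modeled per gene as NB(μ, α) with variance μ + αμ², log link,
and log size-factor offsets; size factors are median-of-ratios over genes
with no zeros, normalized to geometric mean 1 (falling back, with a
warning, to library-size ratios). Designs are treatment-coded with
references Cre⁻ and Input (and the first level of any other factor), so for
the full model `~genotype + fraction + genotype:fraction` the interaction
coefficient *is* the contrast {Cre⁺ log₂FC(IP/Input) − Cre⁻
log₂FC(IP/Input)}; coefficients are reported in log2 units. Multi-level
factors (age) enter as a dummy block and are dropped jointly by the LRT
(df = levels − 1). Genes with fewer than 5 total counts are excluded as
unidentifiable.

**Dispersion.** The gene-wise estimate maximizes the Cox–Reid adjusted
profile likelihood (penalty ½·log det(XᵀWX), W = μ/(1+αμ)) in log α, with
method-of-moments initialization, bounded to [10⁻⁸, 10]; working means come
from a Poisson fit of the full design. Gene-wise estimates are then
moderated: a robust trend α(μ̄) = a₀ + a₁/μ̄ is fit across genes and each
gene's final dispersion is the MAP under a log-normal prior centered on the
trend, whose variance is the observed spread of log gene-wise estimates in
excess of their sampling variability (trigamma((n−p)/2)), floored at 0.25².
Moderation is not optional decoration here: with four samples per design
cell, unshrunk per-gene dispersions make the χ² likelihood-ratio test
sharply anti-conservative (empirical type-I ≈ 0.085–0.089 at nominal 0.05
in the package's own calibration simulations), while the moderated engine
measures 0.04–0.06. `nb_lrt_table(..., shrink=False)` exposes the raw
gene-wise behavior.

**Testing.** The LRT statistic is 2·(llₓᵤₗₗ − llᵣₑ𝒹), clipped at zero, with
both models fit at the same (full-model) dispersion; p-values come from the
χ² upper tail with df = the design-column difference, and BH step-up
adjustment is applied over tested genes. Regional comparisons are realized
as LRTs on region terms through the same machinery (a deliberate
simplification of Wald-style pairwise contrasts — one engine, one nesting
logic; the run metadata says so). The multi-step regional DEG filter
(direction-consistent intersection → IP-enriched in ≥ 1 region → remove
tag-free-enriched non-specific binders) emits a per-step ledger of counts.

**Calibration and its ceiling.** On the standard simulation (2000 genes,
2×2 design, 4 replicates per cell, mean 100, dispersion 0.1) the type-I
rate at nominal 0.05 is 0.04–0.06 and the mean recovered interaction
contrast for planted log₂FC = 2 genes is within ±0.1 of truth.
BH-adjusted sensitivity for those genes is ≈ 0.81–0.86 — and this is
essentially the information limit of the conditions, not an engine defect:
an oracle given the *true* dispersion measures 0.83–0.90 across seeds, and
a normal approximation puts the ceiling near 0.87 (the contrast SE at these
cell means is ≈ 0.47 log2 units, z ≈ 4.25, against a BH-adjusted two-sided
threshold of z ≈ 3.0).

**qPCR.** Abundance in arbitrary units is 2^(40−Cq) (Cq 40 ↔ 1 unit; one
cycle earlier doubles it); undetected reactions stay missing and are never
imputed as Cq 40. ΔΔCq enrichment is (Cq_target,Input − Cq_ref,Input) −
(Cq_target,IP − Cq_ref,IP), positive = IP-enriched, fold = 2^ΔΔCq; shifts
common to both reference wells cancel exactly.

## Particle content estimators

UMI route: (total UMIs / sorted particles) / efficiency, efficiency a
decimal fraction in (0, 1]. The division is deliberate: 1 % combined
extraction/RT efficiency must yield a 100-fold larger estimate than 100 %.
Mass route: (total RNA yield × mRNA mass fraction / MW) × N_A / particles,
with MW = mean length × 320.5 + 159 g/mol (641,159 at 2000 nt). At the
printed input corners these give 0.094 (1 ng, 1 %, 10⁸ particles; 0.1 at
one decimal) and 2.35 (5 ng, 5 %). Both estimators are linear in their
numerators and inverse-linear in particles and efficiency; an efficiency
sweep reproduces the estimate-vs-efficiency curve as a table.

## Synthetic data: scope of the emulation

The generators reproduce the *structure* that the pipeline's logic depends
on — geometry, label bookkeeping, error processes, design factors — under
one top-level seed fanned out into named substreams (CRC32-keyed
SeedSequence children), so every fixture is bit-reproducible. They
deliberately do not emulate: realistic optics beyond an isotropic Gaussian
PSF (no Airy rings, depth-dependent aberration, or anisotropic PSF),
RNAscope amplification variability, autofluorescence or structured
background, alignment errors or multi-mapping reads, index hopping, plate
position effects, or gene-length and GC biases in counts. Imaging noise is
additive Gaussian, not Poisson-limited shot noise. Passing tests therefore
certify the computations' correctness on data matching the model's
assumptions; they do not certify robustness to every artifact of real
microscopes and sequencers. Reads-per-molecule duplication is geometric
(heavy-tailed PCR proxy) with a fixed-count option for exactness tests.

## Numerical choices and degenerate inputs

- Dispersion bounds [10⁻⁸, 10]; Poisson and constant-count genes clamp to
  the lower bound. GLM fits run IRLS to tolerance 10⁻¹⁰, max 100
  iterations; non-converged genes are flagged and excluded from testing.
- LRT statistics are clipped at 0; identical designs give stat 0, p 1.
- Centroid rounding is half-up per axis; neighborhoods clip at image
  borders and report the in-bounds denominator.
- A constant image yields an empty detection result, not an exception;
  empty masks make densities and IF statistics raise explicitly.
- The co-localization threshold is strict (>0.60), the trend fit excludes
  genes at dispersion bounds, and representative-UMI ties break
  lexicographically — all so that reruns are exactly reproducible.
- Default problem sizes (192×256-pixel 16-slice stacks, 2000-gene
  simulations, 200-group collapse checks) were chosen so the full test
  suite and the acceptance script each complete in about a minute on one
  CPU while keeping Monte-Carlo standard errors well inside the asserted
  tolerances.

## Known limitations

- The NB engine is a compact design-level tool: no outlier refitting, no
  independent filtering, no continuous covariates, two-way interactions
  only. It is validated by simulation calibration, not bit-compatibility
  with any external DE framework.
- The detector assumes roughly isotropic blobs within the configured
  diameter range; strongly elongated or overlapping structures (separation
  below ~2σ) will merge.
- Single puncta are not calibrated to molecule counts; a punctum is one or
  a few mRNAs.
- Dendrite traces are inputs (or synthetic); no automated tracing.
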
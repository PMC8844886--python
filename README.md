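# ribofish

Quantification pipeline for subcellular translatome studies in neurons:
where do specific mRNAs sit inside a cell (soma, dendrite, axon), and how
strongly are they engaged by the ribosomes of one genetically tagged cell
type? The package re-implements, as tested and reusable library code, the
bespoke computations such studies rely on:

- **3D FISH puncta quantification** — multiscale Laplacian-of-Gaussian spot
  detection on confocal stacks, a 2-SD immunofluorescence marker mask
  (e.g. tyrosine hydroxylase for dopaminergic neurites), and a 23-voxel
  neighborhood co-localization rule (3×3×3 cube minus the four in-plane
  corners; a punctum counts as inside a neurite when >60 % of its
  neighborhood overlaps the mask). Summaries: puncta per μm³ of
  marker-positive volume, puncta per μm (and per 10 μm) of traced dendrite,
  per-soma counts, and marker-normalized IF intensity for tagged-ribosome
  (eL22-HA) imaging.
- **Plate-based UMI molecule counting** — poly(A) trimming, single-error
  well-barcode correction against a Hamming-distance-≥3 whitelist, exact
  (well, UMI, gene) collapse, and Hamming-distance-1 UMI merging
  (connected components by default, directional count-ratio merging by
  config), yielding a molecular count matrix.
- **Negative-binomial GLM enrichment testing** — per-gene NB GLMs
  (variance μ + αμ²; log link; median-of-ratios size-factor offsets) over
  genotype × fraction designs, with the likelihood-ratio test between the
  full model `~genotype + fraction + genotype:fraction` and a reduced model
  lacking one term. Under treatment coding (references: Cre⁻, Input) the
  interaction coefficient is the contrast of interest,
  {Cre⁺ log₂FC(IP/Input) − Cre⁻ log₂FC(IP/Input)} — the Cre-dependent
  component of ribosome-IP enrichment. Dispersions are estimated gene-wise
  (Cox–Reid adjusted ML) and moderated toward a fitted mean–dispersion
  trend; p-values are BH-adjusted. qPCR helpers provide 2^(40−Cq)
  abundances and ΔΔCq IP/Input enrichment relative to a reference gene.
- **Synaptosome mRNA content** — the two printed estimators of mRNAs per
  sorted particle: UMI-based, (UMIs/particles)/efficiency, and mass-based,
  (yield × %mRNA / MW) × N_A / particles with MW = 2000 nt × 320.5 + 159 =
  641,159 g/mol.
- **Synthetic-data generators** — every input above (two-channel stacks
  with puncta planted inside/outside a tube-shaped neurite, barcode/UMI
  reads with substitution errors and PCR duplication, NB count matrices
  with a genotype-independent fraction effect plus interaction effects on
  a known gene subset, Cq tables) is generated with recorded ground truth,
  so the whole pipeline is testable without any external data.

Intended users: imaging and transcriptomics researchers who want these
analyses as composable, seed-reproducible Python functions rather than
one-off scripts, plus a CLI for batch runs.

## Worked example

```python
from ribofish.simulate import FishStackParams, gen_fish_stack
from ribofish import imaging
from ribofish.particles import estimate_from_umis, estimate_from_total_rna

# a 4×38×51 μm two-channel field: 100 diffraction-limited puncta,
# 70 planted inside a 1.5 μm-radius neurite, SNR 5
params = FishStackParams(n_puncta=100, frac_inside=0.7, seed=42)
field, truth = gen_fish_stack(params)

mask = imaging.compute_mask(field, "IF_TH", k_sd=2.0)
puncta = imaging.detect_puncta(field, "FISH_probe", diameter_range=(0.5, 1.0))
report = imaging.colocalize(puncta, mask)
density = imaging.density_per_mask_volume(report, mask, field.voxel_size)

print(f"detected {len(puncta)} puncta ({truth.inside_flags.sum()} planted inside)")
print(f"co-localized: {report.n_colocalized} ({report.percent_colocalized:.1f}%)")
print(f"density: {density:.3f} puncta per um^3 of marker-positive volume")
print(f"umi estimate: {estimate_from_umis(1, 50, 0.01):.1f} mRNAs per particle")
print(f"mass estimate: {estimate_from_total_rna(1e-9, 1e8, 0.01):.3f}")
```

prints

```
detected 102 puncta (70 planted inside)
co-localized: 70 (68.6%)
density: 0.197 puncta per um^3 of marker-positive volume
umi estimate: 2.0 mRNAs per particle
mass estimate: 0.094
```

The detector recovers the 100 planted spots (plus two noise-boundary
detections); the >60 % neighborhood rule classifies 70 of them as inside
the neurite, matching the planted fraction. The two particle-content
numbers are the printed worked cases: 1 UMI per 50 sorted particles at 1 %
capture efficiency gives 2 mRNAs per particle, and 1 ng of total RNA at
1 % mRNA mass fraction across 10⁸ particles gives 0.094 ≈ 0.1.

## Command line

```sh
ribofish print-config                # all defaults as YAML
ribofish run-all --seed 4 --out out/ # simulate → quantify → count → test → estimate
ribofish quantify-images --in stack.tif --out results/
ribofish count-umis --fastq r1.fastq --whitelist wells.tsv --out counts/
ribofish test-enrichment --counts counts --out de/
ribofish estimate-particles --mode umi
```

`run-all` writes a manifest (seed, config hash, per-stage QC, SHA-256 of
every output) so a run is reproducible bit for bit.

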
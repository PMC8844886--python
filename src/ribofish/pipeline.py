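"""Stage orchestration: run the synthetic stages end to end with a manifest.

``run_pipeline`` executes the requested stages in dependency order
(simulate → images/umis → stats → estimates), writing every intermediate
to disk and recording a manifest (seed, config hash, per-stage QC, output
file hashes) so a run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, io, particles, simulate, stats, umis
from .config import config_hash, default_config, merge_config
from .simulate import CountSimTruth, FishStackParams, ReadSimTruth

__all__ = ["run_pipeline"]

STAGE_ORDER = [
    "simulate",
    "quantify-images",
    "count-umis",
    "test-enrichment",
    "estimate-particles",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, outdir="pipeline_out") -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    cfg = merge_config(default_config(), config or {})
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGE_ORDER if s in cfg["stages"]]

    manifest: dict = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "stages": {},
        "outputs": {},
        "status": "ok",
    }

    state: dict = {}
    try:
        for stage in requested:
            qc = _RUNNERS[stage](cfg, seed, out, state)
            manifest["stages"][stage] = qc
    except Exception as exc:  # downstream stages are aborted
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    io.write_json(out / "manifest.json", manifest)
    return manifest


def _run_simulate(cfg, seed, out, state) -> dict:
    sim = cfg["simulate"]
    qc = {}

    fp = sim["fish"]
    params = FishStackParams(
        shape=tuple(fp["shape"]),
        voxel_size=tuple(fp["voxel_size"]),
        n_puncta=int(fp["n_puncta"]),
        frac_inside=float(fp["frac_inside"]),
        tube_radius_um=float(fp["tube_radius_um"]),
        tube_intensity=float(fp["tube_intensity"]),
        psf_sigma_um=float(fp["psf_sigma_um"]),
        background_mean=float(fp["background_mean"]),
        background_sd=float(fp["background_sd"]),
        snr=float(fp["snr"]),
        seed=seed,
    )
    field, truth = simulate.gen_fish_stack(params)
    io.write_stack(out / "fish_stack.tif", field)
    truth.to_frame().to_csv(out / "fish_truth.tsv", sep="\t", index=False)
    state["fish"] = (field, truth)
    qc["fish_puncta"] = len(truth.puncta_true)

    rp = sim["reads"]
    whitelist = simulate.default_whitelist()
    wells = whitelist[: int(rp["n_wells"])]
    rng = simulate.substream(seed, "pipeline_molecules")
    genes = [f"gene{i:03d}" for i in range(int(rp["n_genes"]))]
    true_molecules = {
        (w, g): int(rng.poisson(rp["mean_molecules"]) + 1) for w in wells for g in genes
    }
    rtruth = ReadSimTruth(
        whitelist=whitelist,
        true_molecules=true_molecules,
        barcode_sub_rate=float(rp["barcode_sub_rate"]),
        umi_sub_rate=float(rp["umi_sub_rate"]),
        mean_duplication=float(rp["mean_duplication"]),
        umi_length=int(rp["umi_length"]),
        seed=seed,
    )
    reads = simulate.gen_reads(rtruth)
    io.write_fastq(out / "reads_R1.fastq", reads)
    reads.to_csv(out / "reads.tsv", sep="\t", index=False)
    pd.Series(whitelist, name="barcode").to_csv(out / "whitelist.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(
        [(w, g, n) for (w, g), n in sorted(true_molecules.items())],
        columns=["well", "gene", "n_molecules"],
    )
    truth_df.to_csv(out / "reads_truth.tsv", sep="\t", index=False)
    sheet = pd.DataFrame(
        {
            "well": wells,
            "genotype": ["CrePos" if i % 2 else "CreNeg" for i in range(len(wells))],
            "fraction": ["IP" if i % 4 >= 2 else "Input" for i in range(len(wells))],
            "age": "NA",
            "region": "VM",
        }
    )
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    state["reads"] = (rtruth, reads, sheet)
    qc["reads"] = len(reads)
    qc["true_molecules"] = int(sum(true_molecules.values()))

    cp = sim["counts"]
    n_genes = int(cp["n_genes"])
    gene_names = CountSimTruth(n_genes=n_genes).gene_names()
    ctruth = CountSimTruth(
        n_genes=n_genes,
        n_per_cell=int(cp["n_per_cell"]),
        baseline_mean=float(cp["baseline_mean"]),
        dispersion=float(cp["dispersion"]),
        fraction_effect_log2=float(cp["fraction_effect_log2"]),
        interaction_genes=gene_names[: int(cp["n_interaction_genes"])],
        interaction_log2fc=float(cp["interaction_log2fc"]),
        seed=seed,
    )
    cm, gene_truth = simulate.gen_counts(ctruth)
    io.write_counts_tsv(out / "counts", cm)
    io.write_counts_mtx(out / "counts_mm", cm)
    gene_truth.to_csv(out / "counts_truth.tsv", sep="\t")
    state["counts"] = (cm, gene_truth)
    qc["count_matrix_shape"] = list(cm.counts.shape)

    qp = sim["qpcr"]
    ab = pd.DataFrame(
        {
            "sample": ["s1"] * 4,
            "gene": ["Th", "Actb", "Th", "Actb"],
            "fraction": ["IP", "IP", "Input", "Input"],
            "abundance": [4096.0, 1024.0, 64.0, 1024.0],
        }
    )
    cq = simulate.gen_qpcr(ab, noise_sd_cq=float(qp["noise_sd_cq"]), seed=seed)
    cq.to_csv(out / "qpcr.tsv", sep="\t", index=False)
    state["qpcr"] = cq
    qc["qpcr_rows"] = len(cq)
    return qc


def _run_quantify(cfg, seed, out, state) -> dict:
    qp = cfg["quantify_images"]
    if "fish" in state:
        field, truth = state["fish"]
    else:
        field = io.read_stack(out / "fish_stack.tif")
        truth = None
    mask = imaging.compute_mask(field, "IF_TH", k_sd=float(qp["k_sd"]))
    puncta = imaging.detect_puncta(
        field,
        "FISH_probe",
        diameter_range=tuple(qp["diameter_range"]),
        n_scales=int(qp["n_scales"]),
        null_quantile=float(qp["null_quantile"]),
    )
    report = imaging.colocalize(puncta, mask)
    density = imaging.density_per_mask_volume(report, mask, field.voxel_size)
    df = puncta.to_frame()
    df["overlap_fraction"] = report.per_punctum["overlap_fraction"]
    df["colocalized"] = report.per_punctum["colocalized"]
    df.to_csv(out / "puncta.tsv", sep="\t", index=False)
    summary = {
        "n_puncta": report.n_puncta,
        "n_colocalized": report.n_colocalized,
        "percent_colocalized": report.percent_colocalized,
        "density_per_um3": density,
        "mask_voxels": mask.n_voxels,
        "mask_threshold": mask.threshold_used,
    }
    io.write_json(out / "image_summary.json", summary)
    return summary


def _run_count_umis(cfg, seed, out, state) -> dict:
    up = cfg["count_umis"]
    if "reads" in state:
        rtruth, reads, sheet = state["reads"]
        whitelist = rtruth.whitelist
    else:
        reads = pd.read_csv(out / "reads.tsv", sep="\t")
        whitelist = list(pd.read_csv(out / "whitelist.tsv", sep="\t")["barcode"])
        sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    molecules, qc = umis.count_reads(
        reads, whitelist, method=up["collapse_method"]
    )
    molecules.to_csv(out / "molecules.tsv", sep="\t", index=False)
    # double-error barcodes can correct into whitelist wells absent from the
    # plate layout; drop them explicitly (tallied) before the hard-checked build
    in_sheet = molecules["well"].isin(set(sheet["well"]))
    qc.extra["molecules_dropped_unused_well"] = int((~in_sheet).sum())
    cm = umis.build_count_matrix(molecules[in_sheet], sheet)
    io.write_counts_tsv(out / "umi_counts", cm)
    io.write_json(out / "umi_qc.json", qc.as_dict())
    return qc.as_dict()


def _run_enrichment(cfg, seed, out, state) -> dict:
    ep = cfg["test_enrichment"]
    if "counts" in state:
        cm, _ = state["counts"]
    else:
        cm = io.read_counts_tsv(out / "counts")
    design = stats.DesignSpec(
        full_terms=list(ep["full_terms"]), reduced_terms=list(ep["reduced_terms"])
    )
    table = stats.nb_lrt_table(cm, cm.metadata, design,
                               min_total_count=int(ep["min_total_count"]))
    table.to_csv(out / "enrichment_results.tsv", sep="\t")
    tested = table[table["status"] == "ok"]
    n_sig = int((tested["padj"] < float(ep["fdr"])).sum())
    qc = {
        "genes_tested": int(len(tested)),
        "genes_low_count": int((table["status"] == "low_count").sum()),
        "genes_not_converged": int((table["status"] == "not_converged").sum()),
        "significant_fdr": n_sig,
    }
    if "qpcr" in state or (out / "qpcr.tsv").exists():
        cq = state.get("qpcr")
        if cq is None:
            cq = pd.read_csv(out / "qpcr.tsv", sep="\t")
        piv = cq.set_index(["gene", "fraction"])["cq"]
        ddcq = stats.ddcq_enrichment(
            piv[("Th", "IP")], piv[("Actb", "IP")],
            piv[("Th", "Input")], piv[("Actb", "Input")],
        )
        qc["qpcr_ddcq_th_vs_actb"] = float(ddcq)
        qc["qpcr_fold_enrichment"] = float(2.0 ** ddcq)
    return qc


def _run_particles(cfg, seed, out, state) -> dict:
    pp = cfg["estimate_particles"]
    u, m = pp["umi"], pp["mass"]
    est_umi = particles.estimate_from_umis(
        float(u["total_umis"]), float(u["sorted_particles"]), float(u["efficiency"])
    )
    est_mass = particles.estimate_from_total_rna(
        float(m["total_rna_yield_g"]),
        float(m["sorted_particles"]),
        float(m["pct_mrna"]),
        float(m["mean_mrna_length_nt"]),
    )
    eff, est = particles.efficiency_sweep(
        float(u["total_umis"]), float(u["sorted_particles"])
    )
    pd.DataFrame({"efficiency": eff, "mrnas_per_particle": est}).to_csv(
        out / "particle_curve.tsv", sep="\t", index=False
    )
    result = {
        "umi_based_mrnas_per_particle": est_umi,
        "mass_based_mrnas_per_particle": est_mass,
        "mass_based_rounded_1dp": float(np.round(est_mass, 1)),
    }
    io.write_json(out / "particle_estimates.json", result)
    return result


_RUNNERS = {
    "simulate": _run_simulate,
    "quantify-images": _run_quantify,
    "count-umis": _run_count_umis,
    "test-enrichment": _run_enrichment,
    "estimate-particles": _run_particles,
}
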
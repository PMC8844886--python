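"""Estimators of mRNA molecules per sorted synaptosomal particle.

Two routes to the same scalar: a UMI-based estimate that scales observed
molecular counts by the combined RNA extraction / reverse-transcription
efficiency, and a mass-based estimate that converts a bulk total-RNA yield
into molecule numbers through the average mRNA molecular weight.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "estimate_from_umis",
    "estimate_from_total_rna",
    "mrna_molecular_weight",
    "efficiency_sweep",
    "AVOGADRO",
    "MW_PER_NT",
    "MW_TERMINAL",
]

AVOGADRO = 6.022e23  # molecules per mol
MW_PER_NT = 320.5  # g/mol per nucleotide
MW_TERMINAL = 159.0  # g/mol 5'-triphosphate terminal correction


def mrna_molecular_weight(mean_length_nt: float = 2000.0) -> float:
    """Average mRNA molecular weight in g/mol: length × 320.5 + 159.

    At the default 2000-nt average this is 641,159 g/mol.
    """
    if mean_length_nt <= 0:
        raise ValueError("mean_length_nt must be positive")
    return mean_length_nt * MW_PER_NT + MW_TERMINAL


def estimate_from_umis(
    total_umis: float, sorted_particles: float, efficiency: float
) -> float:
    """mRNAs per sorted particle from UMI counts.

    (total_umis / sorted_particles) / efficiency, with efficiency as a
    decimal fraction in (0, 1]: observed UMIs undercount true molecules by
    the capture efficiency, so 1% efficiency implies a 100× larger
    estimate than 100%.
    """
    if total_umis <= 0 or sorted_particles <= 0:
        raise ValueError("counts must be positive")
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be a decimal fraction in (0, 1]")
    return (total_umis / sorted_particles) / efficiency


def estimate_from_total_rna(
    total_rna_yield_g: float,
    sorted_particles: float,
    pct_mrna: float,
    mean_mrna_length_nt: float = 2000.0,
) -> float:
    """mRNAs per sorted particle from a bulk total-RNA yield.

    (yield × pct_mrna / MW) × N_A / particles, where pct_mrna is the mass
    fraction of mRNA among total RNA in decimal form (typically 0.01–0.05)
    and MW is the average mRNA molecular weight.
    """
    if total_rna_yield_g <= 0:
        raise ValueError("total RNA yield must be positive")
    if sorted_particles <= 0:
        raise ValueError("sorted_particles must be positive")
    if not 0.0 < pct_mrna < 1.0:
        raise ValueError("pct_mrna is a mass fraction in (0, 1)")
    mw = mrna_molecular_weight(mean_mrna_length_nt)
    return total_rna_yield_g * pct_mrna / mw * AVOGADRO / sorted_particles


def efficiency_sweep(
    total_umis: float,
    sorted_particles: float,
    efficiencies=None,
):
    """UMI-based estimate over an efficiency grid (for the estimate-vs-
    efficiency curve). Returns (efficiencies, estimates) arrays."""
    if efficiencies is None:
        efficiencies = np.logspace(-3, 0, 50)
    eff = np.asarray(efficiencies, dtype=float)
    est = np.array(
        [estimate_from_umis(total_umis, sorted_particles, e) for e in eff]
    )
    return eff, est
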
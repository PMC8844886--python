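"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
two-channel 3D stacks with diffraction-limited puncta planted inside or
outside a tube-shaped neurite, barcode/UMI-tagged reads with substitution
errors and PCR duplication, negative-binomial count matrices with a
genotype-independent fraction (IP vs Input) effect plus a Cre-dependent
interaction on a known gene subset, and qPCR Cq tables. All generators are
deterministic given their seed; each draws from a named substream of the
top-level seed so stages are independently reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import substream
from .types import CountMatrix, DendriteTrace, ImageField

__all__ = [
    "FishStackParams",
    "FishStackTruth",
    "ReadSimTruth",
    "CountSimTruth",
    "gen_fish_stack",
    "gen_dendrite_fixture",
    "gen_reads",
    "gen_counts",
    "gen_qpcr",
    "default_whitelist",
    "hamming",
]

BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    """Hamming distance; 'N' mismatches every base (including 'N')."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y or x == "N" for x, y in zip(a, b))


# --------------------------------------------------------------------------
# FISH / IF image stacks
# --------------------------------------------------------------------------


@dataclass
class FishStackParams:
    """Knobs for one synthetic two-channel stack.

    The imaged scene is a straight tube-shaped neurite (the marker-positive
    structure, rendered in the IF channel) crossing the field along x, with
    FISH puncta planted either well inside or well outside the tube. Peak
    blob amplitude is ``snr × background_sd``.
    """

    shape: tuple[int, int, int] = (16, 192, 256)  # (Z, Y, X) voxels
    voxel_size: tuple[float, float, float] = (0.25, 0.2, 0.2)  # μm
    n_puncta: int = 100
    frac_inside: float = 0.5
    tube_radius_um: float = 1.5
    tube_intensity: float = 200.0
    psf_sigma_um: float = 0.2
    background_mean: float = 100.0
    background_sd: float = 20.0
    snr: float = 5.0
    amplitude: float | None = None  # peak blob intensity; default snr × background_sd
    min_separation_um: float = 0.9
    inside_margin: float = 0.6  # plant inside puncta within this fraction of radius
    outside_margin_um: float = 1.0  # clearance beyond the tube for outside puncta
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive on all axes")
        if any(self.psf_sigma_um < 0.5 * v for v in self.voxel_size):
            raise ValueError(
                "psf_sigma_um smaller than half a voxel on some axis: unresolvable"
            )
        if not 0.0 <= self.frac_inside <= 1.0:
            raise ValueError("frac_inside must be in [0, 1]")
        z, y, x = self.shape
        if not (z <= 20 and y <= 512 and x <= 512):
            raise ValueError("stack exceeds the supported desk-scale size")


@dataclass
class FishStackTruth:
    """Ground truth recorded alongside a generated stack."""

    stack_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    neurite_mask_true: np.ndarray  # boolean (Z, Y, X)
    puncta_true: list[tuple[tuple[float, float, float], bool]]  # ((z,y,x) μm, inside)
    psf_sigma: float
    background_mean: float
    background_sd: float
    seed: int

    @property
    def centroids_um(self) -> np.ndarray:
        if not self.puncta_true:
            return np.zeros((0, 3))
        return np.array([c for c, _ in self.puncta_true], dtype=float)

    @property
    def centroids_vox(self) -> np.ndarray:
        return self.centroids_um / np.asarray(self.voxel_size)

    @property
    def inside_flags(self) -> np.ndarray:
        return np.array([f for _, f in self.puncta_true], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        c = self.centroids_um
        return pd.DataFrame(
            {
                "z_um": c[:, 0] if len(c) else [],
                "y_um": c[:, 1] if len(c) else [],
                "x_um": c[:, 2] if len(c) else [],
                "inside_neurite": self.inside_flags,
            }
        )


def _tube_mask(shape, voxel_size, radius_um) -> tuple[np.ndarray, np.ndarray]:
    """Tube along x centered in (z, y); returns (mask, axis center (z_um, y_um))."""
    nz, ny, _ = shape
    vz, vy, _ = voxel_size
    cz, cy = (nz - 1) / 2 * vz, (ny - 1) / 2 * vy
    zz = np.arange(nz)[:, None] * vz - cz
    yy = np.arange(ny)[None, :] * vy - cy
    r2 = zz**2 + yy**2
    mask = np.broadcast_to((r2 <= radius_um**2)[:, :, None], shape).copy()
    return mask, np.array([cz, cy])


def _render_blobs(shape, voxel_size, centroids_um, amplitude, sigma_um) -> np.ndarray:
    """Sum of isotropic (in μm) Gaussian blobs rendered in local windows."""
    img = np.zeros(shape, dtype=float)
    vs = np.asarray(voxel_size)
    half = np.ceil(4 * sigma_um / vs).astype(int)
    axes_um = [np.arange(n) * v for n, v in zip(shape, vs)]
    for c in np.atleast_2d(centroids_um).reshape(-1, 3):
        cv = c / vs
        lo = np.maximum(np.floor(cv).astype(int) - half, 0)
        hi = np.minimum(np.ceil(cv).astype(int) + half + 1, shape)
        local = [axes_um[i][lo[i] : hi[i]] - c[i] for i in range(3)]
        g = np.exp(
            -(
                local[0][:, None, None] ** 2
                + local[1][None, :, None] ** 2
                + local[2][None, None, :] ** 2
            )
            / (2 * sigma_um**2)
        )
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * g
    return img


def _plant_puncta(params: FishStackParams, mask: np.ndarray, axis_center, rng):
    """Dart-throw centroids inside/outside the tube with a minimum separation."""
    nz, ny, nx = params.shape
    vz, vy, vx = params.voxel_size
    margin = 2.0 * max(params.voxel_size)  # stay clear of the stack border
    bounds_hi = np.array([(nz - 1) * vz, (ny - 1) * vy, (nx - 1) * vx]) - margin
    n_inside = int(round(params.n_puncta * params.frac_inside))
    placed: list[np.ndarray] = []
    flags: list[bool] = []
    min_sep2 = params.min_separation_um**2
    r_in = params.inside_margin * params.tube_radius_um
    r_out = params.tube_radius_um + params.outside_margin_um

    def ok(p):
        return all(np.sum((p - q) ** 2) >= min_sep2 for q in placed)

    for want_inside in ([True] * n_inside) + [False] * (params.n_puncta - n_inside):
        for _ in range(20000):
            p = rng.uniform(margin, bounds_hi)
            d = np.hypot(p[0] - axis_center[0], p[1] - axis_center[1])
            if want_inside and d > r_in:
                continue
            if not want_inside and d < r_out:
                continue
            if ok(p):
                placed.append(p)
                flags.append(want_inside)
                break
        else:
            raise RuntimeError("could not place puncta; loosen density/separation")
    return placed, flags


def gen_fish_stack(params: FishStackParams) -> tuple[ImageField, FishStackTruth]:
    """Generate a two-channel stack (FISH probe + TH-like IF) with truth.

    The IF channel is the tube intensity plus Gaussian noise; the FISH
    channel is a sum of isotropic Gaussian blobs (σ = ``psf_sigma_um``) at
    the planted centroids over a noisy constant background. The returned
    truth records the tube mask and each centroid with its inside/outside
    flag (membership of the centroid voxel in the true mask).
    """
    rng = substream(params.seed, "fish_stack")
    mask, axis_center = _tube_mask(params.shape, params.voxel_size, params.tube_radius_um)
    if params.n_puncta > 0:
        placed, _ = _plant_puncta(params, mask, axis_center, rng)
        centroids = np.array(placed)
    else:
        centroids = np.zeros((0, 3))

    # truth flag = mask membership of the rounded centroid voxel
    flags = []
    for c in centroids:
        v = np.floor(c / np.asarray(params.voxel_size) + 0.5).astype(int)
        v = np.clip(v, 0, np.array(params.shape) - 1)
        flags.append(bool(mask[tuple(v)]))

    amplitude = (
        params.amplitude
        if params.amplitude is not None
        else params.snr * params.background_sd
    )
    fish = np.full(params.shape, params.background_mean, dtype=float)
    if len(centroids):
        fish += _render_blobs(
            params.shape, params.voxel_size, centroids, amplitude, params.psf_sigma_um
        )
    if params.background_sd > 0:
        fish += rng.normal(0.0, params.background_sd, size=params.shape)
        fish = np.clip(fish, 0.0, None)
    th = np.where(mask, params.tube_intensity, params.background_mean).astype(float)
    if params.background_sd > 0:
        th += rng.normal(0.0, params.background_sd, size=params.shape)
        th = np.clip(th, 0.0, None)

    field = ImageField(
        voxels=np.stack([fish, th]),
        voxel_size=params.voxel_size,
        channel_roles={0: "FISH_probe", 1: "IF_TH"},
    )
    truth = FishStackTruth(
        stack_shape=params.shape,
        voxel_size=params.voxel_size,
        neurite_mask_true=mask,
        puncta_true=[(tuple(c), f) for c, f in zip(centroids, flags)],
        psf_sigma=params.psf_sigma_um,
        background_mean=params.background_mean,
        background_sd=params.background_sd,
        seed=params.seed,
    )
    return field, truth


# --------------------------------------------------------------------------
# Dendrite traces
# --------------------------------------------------------------------------


def gen_dendrite_fixture(
    path_length: float,
    puncta_per_um: float = 0.0,
    tortuosity: float = 0.15,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    fill_radius_vox: int = 3,
) -> tuple[DendriteTrace, np.ndarray]:
    """Generate a traced dendrite and puncta planted along it.

    The trace is a persistent 3D random walk (``tortuosity`` is the SD of
    the per-step direction perturbation; 0 gives a straight line) sampled
    at half-voxel arc steps, so the polyline length matches ``path_length``
    to within half a voxel. Planted puncta follow a Poisson process along
    the arc with rate ``puncta_per_um``; their (z, y, x) voxel-unit
    centroids are returned alongside the trace.
    """
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    if puncta_per_um < 0:
        raise ValueError("puncta_per_um must be non-negative")
    rng = substream(seed, "dendrite")
    vs = np.asarray(voxel_size, dtype=float)
    step = float(min(vs)) / 2.0
    n_steps = max(1, int(round(path_length / step)))

    direction = np.array([0.0, 0.0, 1.0])
    pts = [np.zeros(3)]
    for _ in range(n_steps):
        if tortuosity > 0:
            direction = direction + rng.normal(0.0, tortuosity, size=3)
            direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + step * direction)
    pts = np.array(pts)  # μm, origin at start
    actual_length = n_steps * step

    # translate into a padded voxel grid
    pad = (fill_radius_vox + 2) * vs
    origin = pts.min(axis=0) - pad
    pts_um = pts - origin
    vox = np.floor(pts_um / vs + 0.5).astype(int)
    grid_shape = tuple((np.ceil((pts_um.max(axis=0) + pad) / vs)).astype(int) + 1)
    # ordered unique-consecutive voxel path
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = (vox[1:] != vox[:-1]).any(axis=1)
    path = vox[keep]

    mask = np.zeros(grid_shape, dtype=bool)
    mask[tuple(path.T)] = True
    rz = np.arange(-fill_radius_vox, fill_radius_vox + 1)
    ball = (
        rz[:, None, None] ** 2 + rz[None, :, None] ** 2 + rz[None, None, :] ** 2
    ) <= fill_radius_vox**2
    filled = ndimage.binary_dilation(mask, structure=ball)

    n_puncta = rng.poisson(puncta_per_um * actual_length) if puncta_per_um > 0 else 0
    centroids = np.zeros((n_puncta, 3))
    if n_puncta:
        arcs = np.sort(rng.uniform(0.0, actual_length, size=n_puncta))
        idx = arcs / step  # fractional index into pts_um
        lo = np.clip(np.floor(idx).astype(int), 0, len(pts_um) - 2)
        frac = (idx - lo)[:, None]
        centroids = (pts_um[lo] * (1 - frac) + pts_um[lo + 1] * frac) / vs

    trace = DendriteTrace(
        path=path,
        filled_mask=filled,
        path_length=actual_length,
        voxel_size=tuple(vs),
    )
    return trace, centroids


# --------------------------------------------------------------------------
# Barcode / UMI reads
# --------------------------------------------------------------------------

_WHITELIST_SEED = 811_901  # fixed: the whitelist is a resource, not a random draw


def default_whitelist(n: int = 96, length: int = 8, min_dist: int = 3) -> list[str]:
    """Deterministic well-barcode whitelist with pairwise Hamming ≥ ``min_dist``.

    Minimum pairwise distance 3 guarantees unambiguous single-error
    correction. Generated greedily from a fixed internal seed so that every
    run of the pipeline shares one plate layout.
    """
    rng = np.random.default_rng(_WHITELIST_SEED)
    chosen: list[str] = []
    while len(chosen) < n:
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
    return chosen


@dataclass
class ReadSimTruth:
    """Read-simulation parameters plus the true molecule table."""

    whitelist: list[str]
    true_molecules: dict[tuple[str, str], int]  # (well barcode, gene) -> count
    barcode_sub_rate: float = 0.0
    umi_sub_rate: float = 0.0
    mean_duplication: float = 1.0  # reads-per-molecule mean (≥ 1)
    duplication_law: str = "geometric"  # or "fixed": exactly round(mean) reads
    umi_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.whitelist[0])
        if any(len(b) != L for b in self.whitelist):
            raise ValueError("whitelist barcodes must share one length")
        for a, b in itertools.combinations(self.whitelist, 2):
            if hamming(a, b) < 3:
                raise ValueError("whitelist pairwise Hamming distance must be ≥ 3")
        for r in (self.barcode_sub_rate, self.umi_sub_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("substitution rates must be in [0, 1]")
        if self.mean_duplication < 1.0:
            raise ValueError("mean_duplication must be ≥ 1")
        if self.duplication_law not in ("geometric", "fixed"):
            raise ValueError("duplication_law must be 'geometric' or 'fixed'")
        bad = [w for w, _ in self.true_molecules if w not in set(self.whitelist)]
        if bad:
            raise ValueError(f"true molecules reference unknown wells: {bad[:3]}")

    @property
    def barcode_length(self) -> int:
        return len(self.whitelist[0])


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def _code_to_umi(code: int, length: int) -> str:
    s = []
    for _ in range(length):
        s.append(BASES[code % 4])
        code //= 4
    return "".join(s)


def _distinct_umis(n: int, length: int, rng) -> list[str]:
    """True UMIs for one (well, gene): pairwise Hamming distance ≥ 2.

    Distinct molecules carry distinct tags, and separation ≥ 2 makes the
    downstream distance-1 collapse lossless in the error-free limit — the
    regime where tag diversity (4^L) vastly exceeds the molecule count.
    """
    space = 4**length
    if n > space // (1 + 3 * length):
        raise ValueError("too many molecules for the UMI space at separation 2")
    umis: list[str] = []
    taken: set[str] = set()  # chosen UMIs and their distance-1 shells
    while len(umis) < n:
        cand = _code_to_umi(int(rng.integers(0, space)), length)
        if cand in taken:
            continue
        umis.append(cand)
        taken.add(cand)
        for i, base in enumerate(cand):
            for b in BASES:
                if b != base:
                    taken.add(cand[:i] + b + cand[i + 1 :])
    return umis


def gen_reads(truth: ReadSimTruth) -> pd.DataFrame:
    """Simulate barcode/UMI-tagged, gene-annotated reads.

    Each true molecule gets a distinct UMI within its (well, gene) group and
    emits a geometric (or fixed) number of reads (mean ``mean_duplication``);
    observed
    barcode and UMI pass through independent per-base substitution. Columns:
    ``well_barcode_observed, umi_observed, gene, well_true, umi_true``.
    """
    rng = substream(truth.seed, "reads")
    rows = []
    for (well, gene), count in sorted(truth.true_molecules.items()):
        umis = _distinct_umis(count, truth.umi_length, rng)
        for umi in umis:
            if truth.duplication_law == "fixed":
                n_reads = max(1, int(round(truth.mean_duplication)))
            elif truth.mean_duplication == 1.0:
                n_reads = 1
            else:
                n_reads = int(rng.geometric(1.0 / truth.mean_duplication))
            for _ in range(n_reads):
                rows.append(
                    (
                        _mutate(well, truth.barcode_sub_rate, rng),
                        _mutate(umi, truth.umi_sub_rate, rng),
                        gene,
                        well,
                        umi,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["well_barcode_observed", "umi_observed", "gene", "well_true", "umi_true"],
    )


# --------------------------------------------------------------------------
# NB count matrices
# --------------------------------------------------------------------------


@dataclass
class CountSimTruth:
    """Design and per-gene parameters for the NB count simulator.

    The mean model mirrors the ribosome-IP design: a genotype-independent
    fraction effect (non-specific binding common to Cre⁺ and Cre⁻) plus a
    Cre-dependent genotype:fraction interaction restricted to
    ``interaction_genes``. Variance = μ + αμ² per gene.
    """

    n_genes: int = 2000
    n_per_cell: int = 4
    baseline_mean: float | np.ndarray = 100.0
    dispersion: float | np.ndarray = 0.1
    fraction_effect_log2: float | np.ndarray = 0.0
    interaction_genes: Sequence[str] = field(default_factory=list)
    interaction_log2fc: float = 0.0
    age_levels: Sequence[str] = ()
    size_factors: Sequence[float] | None = None
    seed: int = 0

    def gene_names(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("need at least 2 replicates per design cell")
        base = np.broadcast_to(np.asarray(self.baseline_mean, float), (self.n_genes,))
        disp = np.broadcast_to(np.asarray(self.dispersion, float), (self.n_genes,))
        if (base <= 0).any():
            raise ValueError("baseline means must be positive")
        if (disp < 0).any():
            raise ValueError("dispersions must be non-negative")
        unknown = set(self.interaction_genes) - set(self.gene_names())
        if unknown:
            raise ValueError(f"interaction_genes not in gene set: {sorted(unknown)[:3]}")


def gen_counts(truth: CountSimTruth) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw an NB count matrix from the 2×2(×age) ribosome-IP design.

    Cell mean = size_factor × baseline × 2^(fraction_effect·IP)
    × 2^(interaction·IP·CrePos). Returns the count matrix (with metadata)
    and a per-gene truth table (baseline, dispersion, effects, interaction
    flag).
    """
    rng = substream(truth.seed, "counts")
    genes = truth.gene_names()
    base = np.broadcast_to(np.asarray(truth.baseline_mean, float), (truth.n_genes,))
    disp = np.broadcast_to(np.asarray(truth.dispersion, float), (truth.n_genes,))
    frac_eff = np.broadcast_to(
        np.asarray(truth.fraction_effect_log2, float), (truth.n_genes,)
    )
    inter = np.where(np.isin(genes, list(truth.interaction_genes)),
                     truth.interaction_log2fc, 0.0)

    ages = list(truth.age_levels) or [None]
    cells = [
        (g, f, a)
        for a in ages
        for g in ("CreNeg", "CrePos")
        for f in ("Input", "IP")
    ]
    n_samples = len(cells) * truth.n_per_cell
    sf = (
        np.ones(n_samples)
        if truth.size_factors is None
        else np.asarray(truth.size_factors, float)
    )
    if len(sf) != n_samples:
        raise ValueError(f"size_factors must have length {n_samples}")

    meta_rows, cols = [], []
    counts = np.zeros((truth.n_genes, n_samples), dtype=np.int64)
    j = 0
    for geno, frac, age in cells:
        for rep in range(truth.n_per_cell):
            sid = f"{geno}_{frac}" + (f"_{age}" if age else "") + f"_r{rep}"
            is_ip = 1.0 if frac == "IP" else 0.0
            is_pos = 1.0 if geno == "CrePos" else 0.0
            mu = sf[j] * base * 2.0 ** (frac_eff * is_ip + inter * is_ip * is_pos)
            alpha = disp
            pois = alpha <= 1e-12
            col = np.empty(truth.n_genes, dtype=np.int64)
            if pois.any():
                col[pois] = rng.poisson(mu[pois])
            if (~pois).any():
                r = 1.0 / alpha[~pois]
                p = r / (r + mu[~pois])
                col[~pois] = rng.negative_binomial(r, p)
            counts[:, j] = col
            meta_rows.append(
                {
                    "sample_id": sid,
                    "genotype": geno,
                    "fraction": frac,
                    "age": age if age else "NA",
                    "region": "VM",
                    "size_factor_true": sf[j],
                }
            )
            cols.append(sid)
            j += 1

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cols),
        metadata=pd.DataFrame(meta_rows).set_index("sample_id"),
    )
    gene_truth = pd.DataFrame(
        {
            "gene": genes,
            "baseline_mean": base,
            "dispersion": disp,
            "fraction_effect_log2": frac_eff,
            "interaction_log2fc": inter,
            "is_interaction_gene": inter != 0.0,
        }
    ).set_index("gene")
    return cm, gene_truth


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------


def gen_qpcr(
    abundances: pd.DataFrame,
    noise_sd_cq: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn true abundances (arbitrary units) into noisy Cq values.

    Cq = 40 − log2(abundance) + N(0, noise_sd_cq); an abundance of 1 unit
    maps to Cq 40, and each doubling lowers Cq by one cycle. ``abundances``
    needs an ``abundance`` column; other columns (sample, gene, fraction,
    reference flags) pass through.
    """
    if "abundance" not in abundances.columns:
        raise ValueError("abundances needs an 'abundance' column")
    ab = abundances["abundance"].to_numpy(float)
    if (ab <= 0).any():
        raise ValueError("abundances must be positive")
    rng = substream(seed, "qpcr")
    cq = 40.0 - np.log2(ab)
    if noise_sd_cq > 0:
        cq = cq + rng.normal(0.0, noise_sd_cq, size=len(cq))
    out = abundances.copy()
    out["cq"] = cq
    return out
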
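"""Plate-based UMI molecule counting.

Reads carrying a well barcode, a UMI and a gene assignment are turned into
a molecular count matrix in four steps: poly(A) trimming (when raw
sequence is present), single-error well-barcode correction against a
whitelist, exact (well, UMI, gene) collapse, and Hamming-distance-1 UMI
merging within each (well, gene).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import BASES, hamming
from .types import CountMatrix

__all__ = [
    "trim_polyA",
    "correct_barcode",
    "collapse_molecules",
    "build_count_matrix",
    "BarcodeCorrector",
    "UmiQC",
]


def trim_polyA(read_sequence: str, min_run: int = 7) -> str:
    """Trim a 3′ poly(A) tail, tolerating one non-A per 10 bases of run.

    The longest suffix that (a) starts with an A, (b) contains at most
    ``len(suffix) // 10`` non-A bases, and (c) is at least ``min_run`` long
    is removed. The sequence is never lengthened; a pure-A read trims to
    the empty string.
    """
    seq = read_sequence
    n = len(seq)
    non_a = 0
    best_cut = None
    for i in range(n - 1, -1, -1):
        if seq[i] != "A":
            non_a += 1
        run = n - i
        if seq[i] == "A" and run >= min_run and non_a <= run // 10:
            best_cut = i
    return seq[:best_cut] if best_cut is not None else seq


@dataclass
class BarcodeCorrector:
    """Single-error barcode correction against a fixed-length whitelist.

    'N' counts as a mismatch to every base; observations with more than one
    'N' are rejected outright. An observation matching two whitelist
    entries at distance 1 is rejected as ambiguous (kept separate from
    no-neighbor rejects in the QC tallies).
    """

    whitelist: list[str]

    def __post_init__(self) -> None:
        if not self.whitelist:
            raise ValueError("whitelist must be non-empty")
        L = len(self.whitelist[0])
        if any(len(b) != L for b in self.whitelist):
            raise ValueError("whitelist barcodes must share one length")
        self._exact = set(self.whitelist)
        # index: sequences with one position wildcarded -> candidate entries
        self._wild: dict[str, set[str]] = defaultdict(set)
        for bc in self.whitelist:
            for i in range(L):
                self._wild[bc[:i] + "*" + bc[i + 1 :]].add(bc)
        self.length = L

    def correct(self, observed: str) -> tuple[str | None, str]:
        """Return (barcode or None, status ∈ {exact, corrected, ambiguous, distant})."""
        if len(observed) != self.length:
            return None, "distant"
        if observed.count("N") > 1:
            return None, "distant"
        if observed in self._exact:
            return observed, "exact"
        candidates: set[str] = set()
        for i in range(self.length):
            candidates |= self._wild.get(
                observed[:i] + "*" + observed[i + 1 :], set()
            )
        hits = {c for c in candidates if hamming(observed, c) == 1}
        if len(hits) == 1:
            return next(iter(hits)), "corrected"
        if len(hits) > 1:
            return None, "ambiguous"
        return None, "distant"


def correct_barcode(observed: str, whitelist: list[str]) -> tuple[str | None, str]:
    """Functional wrapper around :class:`BarcodeCorrector` for one barcode."""
    return BarcodeCorrector(list(whitelist)).correct(observed)


@dataclass
class UmiQC:
    """Read-accounting for one counting run."""

    reads_in: int = 0
    reads_exact_barcode: int = 0
    reads_corrected_barcode: int = 0
    reads_rejected_ambiguous: int = 0
    reads_rejected_distant: int = 0
    molecules_out: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "reads_in": self.reads_in,
            "reads_exact_barcode": self.reads_exact_barcode,
            "reads_corrected_barcode": self.reads_corrected_barcode,
            "reads_rejected_ambiguous": self.reads_rejected_ambiguous,
            "reads_rejected_distant": self.reads_rejected_distant,
            "molecules_out": self.molecules_out,
        }
        d.update(self.extra)
        return d


def _umi_components(counts: Counter) -> list[list[str]]:
    """Connected components of the Hamming-1 graph over the UMIs in ``counts``.

    Neighbors are found by wildcarding each position, so the cost is
    O(n·L·Σ) rather than O(n²); 'N'-containing UMIs connect to nothing
    (an 'N' mismatches everything, so they sit at distance ≥ 1 from all
    neighbors but distance 1 is still only reached by real base changes).
    """
    umis = list(counts)
    parent = {u: u for u in umis}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    index: dict[str, list[str]] = defaultdict(list)
    for u in umis:
        for i in range(len(u)):
            index[u[:i] + "*" + u[i + 1 :]].append(u)
    # members of one bucket differ only at the wildcarded slot, so any pair is
    # at distance ≤ 1 — except through 'N', which mismatches everything
    for bucket in index.values():
        for j in range(1, len(bucket)):
            for k in range(j):
                if hamming(bucket[j], bucket[k]) == 1:
                    union(bucket[j], bucket[k])
    groups: dict[str, list[str]] = defaultdict(list)
    for u in umis:
        groups[find(u)].append(u)
    return list(groups.values())


def _umi_directional(counts: Counter) -> list[list[str]]:
    """Directional merge: b joins a iff count(a) ≥ 2·count(b) − 1 and d(a,b)=1."""
    order = sorted(counts, key=lambda u: (-counts[u], u))
    index: dict[str, list[str]] = defaultdict(list)
    for u in order:
        for i in range(len(u)):
            index[u[:i] + "*" + u[i + 1 :]].append(u)
    assigned: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for u in order:
        if u in assigned:
            continue
        assigned[u] = u
        groups[u] = [u]
        frontier = [u]
        while frontier:
            cur = frontier.pop()
            for i in range(len(cur)):
                for v in index[cur[:i] + "*" + cur[i + 1 :]]:
                    if v in assigned or hamming(cur, v) != 1:
                        continue
                    if counts[cur] >= 2 * counts[v] - 1:
                        assigned[v] = u
                        groups[u].append(v)
                        frontier.append(v)
    return list(groups.values())


def collapse_molecules(
    reads: pd.DataFrame,
    method: str = "components",
) -> pd.DataFrame:
    """Collapse reads into molecules.

    ``reads`` needs columns ``well`` (corrected barcode), ``umi``, ``gene``.
    Step 1 deduplicates exact (well, UMI, gene) triples keeping read counts;
    step 2 merges UMIs within each (well, gene) that sit within Hamming
    distance one of each other. ``method='components'`` takes connected
    components of the distance-1 graph (the default, literal reading);
    ``method='directional'`` uses the count-ratio rule (merge b into a iff
    count(a) ≥ 2·count(b) − 1). Each merged group is one molecule whose
    representative UMI is the highest-read-count member (ties:
    lexicographically smallest).

    Returns a molecule table with columns
    ``well, gene, representative_umi, n_reads, n_merged_umis``.
    """
    if method not in ("components", "directional"):
        raise ValueError("method must be 'components' or 'directional'")
    cols = ["well", "gene", "representative_umi", "n_reads", "n_merged_umis"]
    if len(reads) == 0:
        return pd.DataFrame(columns=cols)
    for c in ("well", "umi", "gene"):
        if c not in reads.columns:
            raise ValueError(f"reads missing column {c!r}")

    dedup = (
        reads.groupby(["well", "gene", "umi"], sort=True).size().rename("n_reads")
    )
    rows = []
    for (well, gene), sub in dedup.groupby(level=[0, 1], sort=True):
        counts = Counter(
            {umi: int(n) for (_, _, umi), n in sub.items()}
        )
        groups = (
            _umi_components(counts) if method == "components" else _umi_directional(counts)
        )
        for members in groups:
            rep = min(members, key=lambda u: (-counts[u], u))
            rows.append(
                (well, gene, rep, sum(counts[u] for u in members), len(members))
            )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["well", "gene", "representative_umi"]).reset_index(drop=True)


def count_reads(
    reads: pd.DataFrame,
    whitelist: list[str],
    method: str = "components",
) -> tuple[pd.DataFrame, UmiQC]:
    """Barcode-correct a raw read table and collapse it to molecules.

    ``reads`` needs columns ``well_barcode_observed``, ``umi_observed`` and
    ``gene``. Returns the molecule table plus QC tallies.
    """
    corrector = BarcodeCorrector(list(whitelist))
    qc = UmiQC(reads_in=len(reads))
    corrected, statuses = [], []
    for bc in reads["well_barcode_observed"]:
        c, status = corrector.correct(bc)
        corrected.append(c)
        statuses.append(status)
    statuses = np.array(statuses)
    qc.reads_exact_barcode = int((statuses == "exact").sum())
    qc.reads_corrected_barcode = int((statuses == "corrected").sum())
    qc.reads_rejected_ambiguous = int((statuses == "ambiguous").sum())
    qc.reads_rejected_distant = int((statuses == "distant").sum())
    kept = reads.assign(well=corrected).loc[[c is not None for c in corrected]]
    table = kept.rename(columns={"umi_observed": "umi"})[["well", "umi", "gene"]]
    molecules = collapse_molecules(table, method=method)
    qc.molecules_out = len(molecules)
    return molecules, qc


def build_count_matrix(
    molecules: pd.DataFrame, sample_sheet: pd.DataFrame
) -> CountMatrix:
    """Tally molecules into a gene × sample count matrix.

    ``sample_sheet`` is indexed by well barcode (or has a ``well`` column)
    and carries the factor metadata (genotype, fraction, age, region, ...).
    Every well present in ``molecules`` must appear in the sheet; wells
    with no molecules become all-zero columns.
    """
    sheet = sample_sheet
    if "well" in sheet.columns:
        sheet = sheet.set_index("well")
    unknown = sorted(set(molecules["well"]) - set(sheet.index)) if len(molecules) else []
    if unknown:
        raise ValueError(f"molecules reference wells absent from sample sheet: {unknown}")
    samples = list(sheet.index)
    if len(molecules):
        pivot = (
            molecules.groupby(["gene", "well"]).size().unstack(fill_value=0)
        )
        pivot = pivot.reindex(columns=samples, fill_value=0)
    else:
        pivot = pd.DataFrame(0, index=pd.Index([], name="gene"), columns=samples)
    pivot = pivot.astype(int)
    return CountMatrix(counts=pivot, metadata=sheet.copy())
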
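"""Readers and writers for the pipeline's on-disk formats.

TIFF stacks (tifffile), FASTQ (Biopython), TSV tables (pandas),
MatrixMarket count matrices with row/column sidecars (scipy.io), and JSON
QC/manifest blobs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio, sparse

from .types import CountMatrix, ImageField

__all__ = [
    "write_stack",
    "read_stack",
    "write_fastq",
    "read_fastq",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_json",
    "read_json",
]


def write_stack(path, field: ImageField) -> None:
    """Write a (C, Z, Y, X) field as a multi-page TIFF with calibration tags."""
    tifffile.imwrite(
        str(path),
        field.voxels.astype(np.float32),
        metadata={
            "axes": "CZYX",
            "voxel_size_um_zyx": list(field.voxel_size),
            "channel_roles": {str(k): v for k, v in field.channel_roles.items()},
        },
    )


def read_stack(path, voxel_size=None, channel_roles=None) -> ImageField:
    """Read a multi-page TIFF back into an ImageField.

    Calibration and channel roles come from the embedded metadata when
    present; explicit arguments override.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 3:
        arr = arr[None]
    vs = voxel_size or tuple(meta.get("voxel_size_um_zyx", (1.0, 1.0, 1.0)))
    roles = channel_roles or {
        int(k): v for k, v in meta.get("channel_roles", {"0": "FISH_probe"}).items()
    }
    return ImageField(arr.astype(float), tuple(vs), roles)


def write_fastq(path, reads: pd.DataFrame, barcode_col="well_barcode_observed",
                umi_col="umi_observed", gene_col="gene") -> None:
    """Write read 1 (barcode ‖ UMI, Phred 33 'I') with the gene tag in the header."""
    records = []
    for i, row in enumerate(reads.itertuples()):
        seq = getattr(row, barcode_col) + getattr(row, umi_col)
        rec = SeqRecord(
            Seq(seq),
            id=f"read{i:08d}",
            description=f"gene={getattr(row, gene_col)}",
        )
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path, barcode_length: int, umi_length: int) -> pd.DataFrame:
    """Parse read-1 FASTQ into (well_barcode_observed, umi_observed, gene)."""
    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq)
        gene = None
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene = tok[5:]
        rows.append(
            (seq[:barcode_length], seq[barcode_length : barcode_length + umi_length], gene)
        )
    return pd.DataFrame(rows, columns=["well_barcode_observed", "umi_observed", "gene"])


def write_counts_tsv(prefix, cm: CountMatrix) -> None:
    """Write counts as ``<prefix>.counts.tsv`` with a metadata sidecar."""
    prefix = Path(prefix)
    cm.counts.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    cm.metadata.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t")


def read_counts_tsv(prefix) -> CountMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index_col=0)
    return CountMatrix(counts=counts, metadata=meta)


def write_counts_mtx(prefix, cm: CountMatrix) -> None:
    """Write counts as MatrixMarket plus gene/sample sidecar TSVs."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(cm.counts.values))
    pd.Series(cm.counts.index, name="gene").to_csv(
        prefix.with_suffix(".genes.tsv"), sep="\t", index=False
    )
    cm.metadata.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t")


def read_counts_mtx(prefix) -> CountMatrix:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(int)
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t")["gene"]
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index_col=0)
    return CountMatrix(
        counts=pd.DataFrame(mat, index=list(genes), columns=list(meta.index)),
        metadata=meta,
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
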
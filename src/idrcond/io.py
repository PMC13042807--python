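"""File-format adapters: FASTA proteins, disorder-score tracks, line
scans, ROI tables, and TIFF images."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .grammar import DisorderTrack, ProteinRecord
from .imaging import LineScan, NucleusImage

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_disorder_track",
    "read_linescan",
    "read_image",
    "write_image",
]


def read_fasta(path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def read_disorder_track(path, protein_id: str | None = None) -> DisorderTrack:
    """Two-column TSV/CSV: 1-based residue index, disorder score."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need (residue_index, score) columns")
    if isinstance(df.iloc[0, 0], str):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    idx = df.iloc[:, 0].astype(int).to_numpy()
    scores = df.iloc[:, 1].astype(float).to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: residue indices must run 1..L")
    return DisorderTrack(protein_id or str(path), scores)


def read_linescan(path) -> LineScan:
    """One-column CSV of intensities (optional header)."""
    df = pd.read_csv(path, header=None, comment="#")
    col = df.iloc[:, -1]
    if isinstance(col.iloc[0], str):
        col = col.iloc[1:]
    return LineScan(col.astype(float).to_numpy())


def read_image(image_path, mask_path) -> NucleusImage:
    img = tifffile.imread(str(image_path)).astype(float)
    mask = tifffile.imread(str(mask_path)) > 0
    return NucleusImage(img, mask)


def write_image(image: NucleusImage, image_path, mask_path) -> None:
    tifffile.imwrite(str(image_path),
                     np.clip(image.intensity, 0, 65535).astype(np.uint16))
    tifffile.imwrite(str(mask_path), image.mask.astype(np.uint16) * 65535)
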
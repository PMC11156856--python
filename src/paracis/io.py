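"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open on disk (BED convention). Dense matrices
travel as TSV, sparse cell-by-gene matrices as MatrixMarket with row/column
label sidecars, and contact matrices as upper-triangle (bin_i, bin_j, count)
triplets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import sparse
from scipy.io import mmread, mmwrite

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(str(path), sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


def track_to_bedgraph(values: np.ndarray, chrom: str) -> pd.DataFrame:
    """Run-length encode a per-bp track into bedGraph rows (zero runs skipped)."""
    values = np.asarray(values, dtype=float)
    edges = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(values)]])
    rows = [
        (chrom, int(s), int(e), float(values[s]))
        for s, e in zip(starts, ends)
        if values[s] != 0
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def bedgraph_to_track(df: pd.DataFrame, length: int) -> np.ndarray:
    out = np.zeros(length)
    for _, row in df.iterrows():
        out[int(row["start"]) : int(row["end"])] = row["value"]
    return out


def write_cell_matrix(binary: pd.DataFrame, prefix) -> None:
    """Write a cell-by-gene matrix as MTX plus row (cell) and column (gene) files."""
    prefix = Path(prefix)
    mat = sparse.csr_matrix(binary.to_numpy(dtype=np.int64))
    mmwrite(str(prefix.with_suffix(".mtx")), mat)
    prefix.with_suffix(".cells.txt").write_text(
        "\n".join(str(i) for i in binary.index) + "\n"
    )
    prefix.with_suffix(".genes.txt").write_text("\n".join(binary.columns) + "\n")


def read_cell_matrix(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = mmread(str(prefix.with_suffix(".mtx"))).toarray()
    cells = prefix.with_suffix(".cells.txt").read_text().split()
    genes = prefix.with_suffix(".genes.txt").read_text().split()
    return pd.DataFrame(mat, index=cells, columns=genes)


def write_contact_triplets(counts: np.ndarray, path, region: str = "", bin_size: int = 0) -> None:
    """Upper-triangle (bin_i, bin_j, count) triplets with a matrix-shape header."""
    counts = np.asarray(counts)
    i, j = np.triu_indices(counts.shape[0])
    nz = counts[i, j] != 0
    with open(path, "w") as fh:
        fh.write(f"# region={region} bin_size={bin_size} n_bins={counts.shape[0]}\n")
        for bi, bj in zip(i[nz], j[nz]):
            fh.write(f"{bi}\t{bj}\t{counts[bi, bj]:g}\n")


def read_contact_triplets(path) -> tuple[np.ndarray, dict]:
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                k, _, v = token.partition("=")
                meta[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    rows = [line.split("\t") for line in body.strip().splitlines() if line.strip()]
    i = np.array([int(r[0]) for r in rows])
    j = np.array([int(r[1]) for r in rows])
    v = np.array([float(r[2]) for r in rows])
    n = int(meta.get("n_bins", max(i.max(), j.max()) + 1))
    counts = np.zeros((n, n))
    counts[i, j] = v
    counts[j, i] = v
    meta["n_bins"] = n
    if "bin_size" in meta:
        meta["bin_size"] = int(meta["bin_size"])
    return counts, meta


def write_coordinate_map(cmap, path) -> None:
    """Long-form TSV: paralog, paralog_pos, consensus_pos (-1 = unmapped)."""
    rows = []
    for name, arr in cmap.maps.items():
        for pos, cons in enumerate(arr):
            rows.append((name, pos, int(cons)))
    pd.DataFrame(rows, columns=["paralog", "paralog_pos", "consensus_pos"]).to_csv(
        str(path), sep="\t", index=False
    )


def read_alignment_table(path) -> pd.DataFrame:
    """SAM-like TSV: read_id, region, alignment score, read length, flags, tlen."""
    return pd.read_csv(str(path), sep="\t")
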
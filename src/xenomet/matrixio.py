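"""Matrix and table I/O.

Count matrices travel either as a plain TSV (genes in rows, samples in
columns, header row of sample ids, first column of gene ids) or as a
MatrixMarket ``.mtx`` file with sidecar one-column gene/sample TSVs.
Annotation tables are TSVs with documented columns.
"""

from __future__ import annotations

import os

import pandas as pd
import scipy.io
import scipy.sparse


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV (gene ids in column 0)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> pd.DataFrame:
    """Read genes x samples counts from MatrixMarket + sidecar index files."""
    mat = scipy.io.mmread(os.fspath(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    samples = pd.read_csv(samples_path, sep="\t", header=None)[0].tolist()
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return pd.DataFrame(mat, index=genes, columns=samples)


def write_counts_mtx(
    counts: pd.DataFrame,
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> None:
    scipy.io.mmwrite(os.fspath(mtx_path), scipy.sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(samples_path, sep="\t", header=False, index=False)


def read_gene_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, species, length_bp."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return df.set_index("gene_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, class."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


def read_signature(path: str | os.PathLike) -> list[str]:
    """Signature gene list: plain text, one gene id per line, blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
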
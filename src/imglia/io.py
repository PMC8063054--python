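"""Readers and writers for the pipeline's tabular artifacts.

Canonical on-disk format is TSV (header row, UTF-8); count matrices are
also accepted as MatrixMarket coordinate triplets with sidecar gene and
sample lists.  Gene lists are plain text, one symbol per line.  All
cross-dataset gene matching is by whitespace-trimmed, case-folded symbol.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CountMatrix,
    FormatError,
    GeneList,
    MetadataError,
    NormalizedMatrix,
    normalize_symbol,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gene_list",
    "write_gene_list",
    "read_gene_lengths",
    "read_ct_table",
    "write_normalized",
    "read_normalized",
    "merge_datasets",
    "union_gene_lists",
]


def _read_meta(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise MetadataError("metadata table needs a 'sample_id' column")
    return meta.set_index("sample_id")


def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a gene×sample TSV count table plus its sample metadata.

    First column = gene ids, header row = sample ids.  Non-integer
    cells, duplicate ids and samples absent from the metadata are
    rejected with errors naming the offenders.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str).rename(None)
    table.columns.name = None
    non_numeric = table.columns[
        [not np.issubdtype(dt, np.number) for dt in table.dtypes]
    ]
    if len(non_numeric):
        raise FormatError(
            "non-numeric count values in samples: " + ", ".join(map(str, non_numeric))
        )
    return CountMatrix(table, _read_meta(meta_path))


def write_counts(m: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    m.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    m.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    meta_path: str | Path,
) -> CountMatrix:
    """MatrixMarket coordinate triplet + sidecar gene/sample id lists."""
    mat = scipy.io.mmread(mtx_path)
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(samples)):
        raise FormatError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(samples)} samples"
        )
    table = pd.DataFrame(dense, index=genes, columns=samples)
    return CountMatrix(table, _read_meta(meta_path))


def write_counts_mtx(
    m: CountMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    meta_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(m.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(m.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(m.sample_ids) + "\n")
    m.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    symbols = Path(path).read_text().splitlines()
    return GeneList.from_symbols(name or Path(path).stem, symbols)


def write_gene_list(gl: GeneList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gl.symbols)) + "\n")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """TSV of gene_id → transcript length in bp; lengths must be > 0."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    lengths = table.iloc[:, 0]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0]
        raise FormatError("non-positive gene lengths: " + ", ".join(map(str, bad)))
    return lengths.astype(float)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"condition", "replicate", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError("CT table missing columns: " + ", ".join(sorted(missing)))
    return table


def write_normalized(m: NormalizedMatrix, path: str | Path, log_path: str | Path) -> None:
    """Matrix as TSV with a sidecar JSON transform log."""
    m.values.rename_axis("gene_id").to_csv(path, sep="\t")
    Path(log_path).write_text(json.dumps(m.transform_log, indent=1, sort_keys=True))


def read_normalized(
    path: str | Path, log_path: str | Path, meta_path: str | Path
) -> NormalizedMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    log = json.loads(Path(log_path).read_text())
    return NormalizedMatrix(values, _read_meta(meta_path), log)


def merge_datasets(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Merge two studies on the intersection of their gene symbols.

    Gene symbols are matched case-insensitively after trimming; samples
    are concatenated and keep their study labels.  An empty intersection
    raises, since it almost always signals a gene-identifier mismatch
    (e.g. Ensembl ids in one table, symbols in the other).
    """
    norm_a = {normalize_symbol(g): g for g in a.gene_ids}
    norm_b = {normalize_symbol(g): g for g in b.gene_ids}
    shared = sorted(set(norm_a) & set(norm_b))
    if not shared:
        raise FormatError(
            "no genes shared between the datasets; check that both use the "
            "same identifier system (gene symbols)"
        )
    dup_samples = set(a.sample_ids) & set(b.sample_ids)
    if dup_samples:
        raise FormatError(
            "sample ids present in both datasets: " + ", ".join(sorted(dup_samples))
        )
    left = a.counts.loc[[norm_a[g] for g in shared]]
    left.index = shared
    right = b.counts.loc[[norm_b[g] for g in shared]]
    right.index = shared
    counts = pd.concat([left, right], axis=1)
    meta = pd.concat([a.sample_meta, b.sample_meta])
    return CountMatrix(counts, meta)


def union_gene_lists(lists: Sequence[GeneList], name: str = "union") -> GeneList:
    """Deduplicated union of gene lists under symbol normalization."""
    if not lists:
        raise FormatError("union_gene_lists needs at least one list")
    symbols: set[str] = set()
    for gl in lists:
        symbols |= gl.symbols
    return GeneList(name=name, symbols=frozenset(symbols))
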
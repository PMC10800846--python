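"""Readers and writers for the standard on-disk formats.

Count tables are written as TSV (rows = OTUs, columns = samples) and as BIOM
v2.1; metadata, expression and distance matrices as TSV; trees as Newick;
ground truth and result traces as JSON. Readers auto-detect row/column
orientation by matching ids against the metadata and validate ids across
files, reporting *all* offending ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from microsig.containers import ExpressionMatrix, InputError, OtuTable
from microsig.synthetic import GroundTruth

# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_counts_tsv(table: OtuTable, path) -> None:
    # rename_axis copies; mutating .index.name after .T would rename the
    # caller's columns (the transpose shares the axis Index objects)
    table.counts.T.rename_axis("otu_id").to_csv(path, sep="\t")


def write_metadata_tsv(table: OtuTable, path) -> None:
    meta = table.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t")


def write_biom(table: OtuTable, path) -> None:
    """Write the count table as BIOM v2.1 (HDF5)."""
    import biom
    import h5py

    bt = biom.Table(
        table.counts.to_numpy().T,
        observation_ids=table.otu_ids,
        sample_ids=table.sample_ids,
    )
    with h5py.File(path, "w") as fh:
        bt.to_hdf5(fh, generated_by="microsig")


def read_biom(path, meta: pd.DataFrame) -> OtuTable:
    import biom

    bt = biom.load_table(str(path))
    counts = pd.DataFrame(
        bt.matrix_data.toarray().T.astype(int),
        index=list(bt.ids("sample")),
        columns=list(bt.ids("observation")),
    )
    return OtuTable(counts, meta.loc[counts.index])


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.T.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6f")


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "discriminative_otus": truth.discriminative_otus,
        "boosted_line": truth.boosted_line,
        "exclusive_otus": truth.exclusive_otus,
        "linked_genes": truth.linked_genes,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        discriminative_otus=payload["discriminative_otus"],
        boosted_line=payload["boosted_line"],
        exclusive_otus=payload["exclusive_otus"],
        linked_genes=payload["linked_genes"],
    )


def write_distance_tsv(dm, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, set, tuple)):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# readers with orientation detection
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _orient(df: pd.DataFrame, sample_ids: set, what: str) -> pd.DataFrame:
    """Return the matrix with samples as rows, matching ids against metadata."""
    rows, cols = set(df.index), set(df.columns)
    if rows & sample_ids and not cols & sample_ids:
        oriented = df
    elif cols & sample_ids:
        oriented = df.T
    else:
        raise InputError(f"{what}: no ids match the metadata sample ids")
    missing = sorted(sample_ids - set(oriented.index))
    extra = sorted(set(oriented.index) - sample_ids)
    if missing or extra:
        raise InputError(f"{what}: sample ids missing={missing} unexpected={extra}")
    return oriented.loc[sorted(oriented.index)]


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise InputError("duplicate sample ids in metadata")
    return meta


def read_counts(path, meta: pd.DataFrame) -> OtuTable:
    path = Path(path)
    if path.suffix == ".biom":
        return read_biom(path, meta)
    df = _read_matrix_tsv(path)
    oriented = _orient(df, set(meta.index), "count table")
    return OtuTable(oriented.astype(int), meta.loc[oriented.index])


def read_expression(path, meta: pd.DataFrame) -> ExpressionMatrix:
    df = _read_matrix_tsv(path)
    oriented = _orient(df, set(meta.index), "expression matrix")
    return ExpressionMatrix(oriented.astype(float))


def read_inputs(counts_path, metadata_path, tree_path=None, expression_path=None):
    """Read and cross-validate the pipeline inputs.

    Sample ids must be consistent across counts/metadata/expression; every OTU
    must be a leaf of the tree. Mismatches are reported exhaustively.
    """
    meta = read_metadata_tsv(metadata_path)
    table = read_counts(counts_path, meta)
    tree = expr = None
    if tree_path is not None:
        tree = read_tree(tree_path)
        leaves = {t.name for t in tree.tips()}
        missing = sorted(set(table.otu_ids) - leaves)
        if missing:
            raise InputError(f"OTUs missing from tree: {missing}")
    if expression_path is not None:
        expr = read_expression(expression_path, meta)
    return table, tree, expr
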
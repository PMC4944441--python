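"""Readers and writers for the pipeline's tabular and tree formats.

On disk, abundance tables are tab-delimited with taxa on rows: the
first column holds the lineage string (header ``#taxon``) and the
remaining columns are samples.  Metadata is a plain TSV with one row
per sample.  Trees are newick with branch lengths, read through
scikit-bio.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    REQUIRED_METADATA_COLUMNS,
    CohortMetadata,
    TaxonTable,
    ValidationError,
)

log = logging.getLogger("dysbiome")

TAXON_COLUMN = "#taxon"


def read_taxon_table(path: str | Path, value_kind: str = "counts") -> TaxonTable:
    """Read a taxa-on-rows TSV into a :class:`TaxonTable`.

    The first column must hold lineage strings; the header row holds
    sample IDs.  All body cells must be numeric and non-negative.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse table {path}: {exc}") from exc
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate lineage rows in {path}: {dupes}")
    try:
        body = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    table = TaxonTable(body.T, value_kind=value_kind)
    log.info("read taxon table %s: %d samples x %d taxa (%s)",
             path, table.n_samples, table.n_taxa, value_kind)
    return table


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    out = table.data.T
    out.index.name = TAXON_COLUMN
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: str | Path) -> CohortMetadata:
    """Read and validate the per-sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata {path} missing columns: {missing}")
    md = CohortMetadata(df)
    log.info("read metadata %s: %d samples, %d subjects",
             path, len(md.data), len(md.subjects))
    return md


def write_metadata(md: CohortMetadata, path: str | Path) -> None:
    md.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted newick tree, requiring branch lengths on every
    non-root branch (lengths must be >= 0)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValidationError(f"cannot parse newick {path}: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"tree {path} has a branch without a length (at "
                f"{node.name or 'internal node'}); branch lengths are required"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length in {path}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def prune_tree_to_taxa(tree: TreeNode, taxa: list[str]) -> TreeNode:
    """Prune a tree to the intersection of its leaves with ``taxa``.

    Raises if the intersection is empty.
    """
    names = {t.name for t in tree.tips()}
    keep = [t for t in taxa if t in names]
    if not keep:
        raise ValidationError("no overlap between tree leaves and table taxa")
    pruned = tree.shear(keep)
    pruned.prune()
    if pruned.length is None:
        pruned.length = 0.0
    return pruned
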
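"""Genus collapsing, relative abundance, and the sample/prevalence filters.

The canonical preprocessing order is: drop low-depth samples (counts),
collapse OTU rows to genus, convert to frequencies, then apply the
prevalence filter.  Genus identity is the full lineage truncated at
the genus rank, so two unnamed ``g__`` genera from different families
remain distinct taxa.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import RANK_PREFIXES, TaxonTable, ValidationError

log = logging.getLogger("dysbiome")

_GENUS_DEPTH = 6  # k,p,c,o,f,g


def exclude_low_depth_samples(table: TaxonTable, min_reads: int) -> TaxonTable:
    """Drop samples whose total read count is below ``min_reads``.

    The threshold is exclusive: a sample with exactly ``min_reads``
    reads is kept ("fewer than" semantics).
    """
    if table.value_kind != "counts":
        raise ValidationError("depth filtering requires a count table")
    depths = table.depths()
    keep = depths >= min_reads
    dropped = depths.index[~keep].tolist()
    if dropped:
        log.warning("excluded %d low-depth samples (<%d reads): %s",
                    len(dropped), min_reads, dropped)
    if not keep.any():
        raise ValidationError("all samples fall below the read-depth threshold")
    return TaxonTable(table.data.loc[keep], value_kind="counts")


def genus_lineage(lineage: str) -> str:
    """Truncate a lineage string at the genus rank.

    Rank prefixes beyond genus (e.g. ``s__``) are discarded; missing
    trailing ranks are left absent.  A lineage carrying no recognized
    rank prefix at all is rejected.
    """
    parts = [p.strip() for p in lineage.split(";")]
    if not any(p[:3] in RANK_PREFIXES for p in parts if len(p) >= 3):
        raise ValidationError(f"lineage lacks rank prefixes: {lineage!r}")
    kept = []
    for part in parts:
        prefix = part[:3]
        if prefix in RANK_PREFIXES:
            kept.append(part)
        if prefix == "g__":
            break
    return ";".join(kept[:_GENUS_DEPTH])


def collapse_to_genus(table: TaxonTable) -> TaxonTable:
    """Sum rows that share the same genus-truncated lineage.

    Per-sample totals are conserved exactly.  First-appearance order of
    the collapsed lineages is preserved.
    """
    mapping = [genus_lineage(lin) for lin in table.taxon_lineages]
    grouped = table.data.T.groupby(mapping, sort=False).sum().T
    return TaxonTable(grouped, value_kind=table.value_kind)


def relative_abundance(table: TaxonTable) -> TaxonTable:
    """Divide each sample by its total so rows sum to 1."""
    totals = table.data.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"cannot normalize all-zero samples: {zero}")
    freq = table.data.div(totals, axis=0)
    return TaxonTable(freq, value_kind="frequencies")


def prevalence_filter(table: TaxonTable, threshold: float) -> TaxonTable:
    """Keep taxa whose maximum per-sample relative abundance is
    strictly greater than ``threshold``; column order preserved."""
    if table.value_kind not in ("frequencies", "frequencies_filtered"):
        raise ValidationError("prevalence filter requires a frequency table")
    maxima = table.data.max(axis=0)
    keep = maxima > threshold
    log.info("prevalence filter >%g: kept %d / %d taxa",
             threshold, int(keep.sum()), table.n_taxa)
    filtered = table.data.loc[:, keep]
    # rows need no longer sum to 1 once columns are dropped
    return TaxonTable(filtered, value_kind="frequencies_filtered")


def prevalence_report(table: TaxonTable, threshold: float) -> pd.DataFrame:
    """Per-taxon filter report: max abundance and kept flag."""
    maxima = table.data.max(axis=0)
    return pd.DataFrame({
        "taxon": maxima.index,
        "max_abundance": maxima.to_numpy(),
        "kept": (maxima > threshold).to_numpy(),
    })
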
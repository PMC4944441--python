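"""Shannon alpha diversity, the microbial dysbiosis (MD) index, and
repeated-rarefaction robustness metrics.

The MD index is the log10 ratio of the summed relative abundance of
taxa increased in Crohn's disease to the summed relative abundance of
taxa decreased in Crohn's disease.  Increased-in-CD taxa are the
families Enterobacteriaceae, Pasteurellaceae, Fusobacteriaceae,
Neisseriaceae, Veillonellaceae and Gemellaceae; decreased-in-CD taxa
are the orders Bacteroidales and Clostridiales (excluding the family
Veillonellaceae) plus the families Erysipelotrichaceae and
Bifidobacteriaceae.  A pseudocount keeps the log finite when either
sum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TaxonTable, ValidationError, stage_rng

__all__ = [
    "DysbiosisMembership",
    "DEFAULT_MEMBERSHIP",
    "shannon",
    "classify_taxa",
    "md_index",
    "rarefy",
    "rarefaction_median_metric",
    "sample_metrics",
]


@dataclass(frozen=True)
class DysbiosisMembership:
    """Taxon sets defining the MD index.

    Entries are ``(rank, name)`` pairs matched against rank-prefixed
    lineage fields (e.g. ``("family", "Veillonellaceae")`` matches any
    lineage containing ``f__Veillonellaceae``).  ``excluded_from_decreased``
    carves exceptions out of the decreased set; by construction
    Veillonellaceae is increased, never decreased.
    """

    increased: frozenset = frozenset({
        ("family", "Enterobacteriaceae"),
        ("family", "Pasteurellaceae"),
        ("family", "Fusobacteriaceae"),
        ("family", "Neisseriaceae"),
        ("family", "Veillonellaceae"),
        ("family", "Gemellaceae"),
    })
    decreased: frozenset = frozenset({
        ("order", "Bacteroidales"),
        ("order", "Clostridiales"),
        ("family", "Erysipelotrichaceae"),
        ("family", "Bifidobacteriaceae"),
    })
    excluded_from_decreased: frozenset = frozenset({
        ("family", "Veillonellaceae"),
    })


DEFAULT_MEMBERSHIP = DysbiosisMembership()

_RANK_TO_PREFIX = {
    "kingdom": "k__", "phylum": "p__", "class": "c__",
    "order": "o__", "family": "f__", "genus": "g__",
}


def shannon(abundances: np.ndarray, log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log(p_i) of one sample.

    Accepts counts or frequencies; the vector is normalized first.
    Zero entries contribute nothing.  ``log_base`` 2 gives bits.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValidationError("zero-sum abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(log_base))


def _lineage_fields(lineage: str) -> set[str]:
    return {part.strip() for part in lineage.split(";")}


def _matches(fields: set[str], entries) -> bool:
    for rank, name in entries:
        if _RANK_TO_PREFIX[rank] + name in fields:
            return True
    return False


def classify_taxa(
    lineages: list[str],
    membership: DysbiosisMembership = DEFAULT_MEMBERSHIP,
) -> np.ndarray:
    """Label each lineage ``increased`` / ``decreased`` / ``neither``.

    A lineage is increased if it contains any increased entry;
    decreased if it matches a decreased entry and none of the
    exclusions; otherwise neither.  Matching is by exact rank-prefixed
    name, case-sensitive, after trimming whitespace.
    """
    labels = np.empty(len(lineages), dtype=object)
    for i, lineage in enumerate(lineages):
        fields = _lineage_fields(lineage)
        if _matches(fields, membership.increased):
            labels[i] = "increased"
        elif (_matches(fields, membership.decreased)
              and not _matches(fields, membership.excluded_from_decreased)):
            labels[i] = "decreased"
        else:
            labels[i] = "neither"
    return labels


def md_index(
    abundances: np.ndarray,
    labels: np.ndarray,
    pseudocount: float = 1e-5,
) -> float:
    """Microbial dysbiosis index of one sample.

    log10 of (relative abundance summed over increased taxa +
    pseudocount) over (summed over decreased taxa + pseudocount).
    Scale-invariant in the input vector.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValidationError("zero-sum abundance vector")
    labels = np.asarray(labels)
    inc = x[labels == "increased"].sum() / total
    dec = x[labels == "decreased"].sum() / total
    return float(np.log10((inc + pseudocount) / (dec + pseudocount)))


def rarefy(counts: np.ndarray, depth: int,
           rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth``
    reads (multivariate hypergeometric draw)."""
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        rounded = np.rint(x).astype(np.int64)
        if not np.allclose(x, rounded, atol=1e-9):
            raise ValidationError("rarefaction requires integer counts")
        x = rounded
    if (x < 0).any():
        raise ValidationError("negative counts")
    total = int(x.sum())
    if total < depth:
        raise ValidationError(
            f"sample has {total} reads, fewer than rarefaction depth {depth}"
        )
    return rng.multivariate_hypergeometric(x, depth)


_METRICS = {"shannon", "md_index"}


def rarefaction_median_metric(
    counts: np.ndarray,
    depth: int,
    reps: int,
    metric: str,
    rng: np.random.Generator,
    *,
    labels: np.ndarray | None = None,
    log_base: float = 2.0,
    pseudocount: float = 1e-5,
) -> float:
    """Median of a per-sample metric over ``reps`` independent
    rarefactions of one count vector.

    ``metric`` is ``shannon`` or ``md_index`` (the latter needs the
    per-taxon ``labels``).  Rarefied draws are vectorized; the median
    is taken across replicates.
    """
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        x = np.rint(x).astype(np.int64)
    total = int(x.sum())
    if total < depth:
        raise ValidationError(
            f"sample has {total} reads, fewer than rarefaction depth {depth}"
        )
    draws = rng.multivariate_hypergeometric(x, depth, size=reps).astype(float)
    if metric == "shannon":
        p = draws / depth
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        values = -terms.sum(axis=1) / np.log(log_base)
    else:
        if labels is None:
            raise ValidationError("md_index needs per-taxon labels")
        labels = np.asarray(labels)
        inc = draws[:, labels == "increased"].sum(axis=1) / depth
        dec = draws[:, labels == "decreased"].sum(axis=1) / depth
        values = np.log10((inc + pseudocount) / (dec + pseudocount))
    return float(np.median(values))


def sample_metrics(
    genus_counts: TaxonTable,
    *,
    membership: DysbiosisMembership = DEFAULT_MEMBERSHIP,
    log_base: float = 2.0,
    pseudocount: float = 1e-5,
    rarefaction_depth: int | None = None,
    rarefaction_reps: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample metric table: depth, Shannon, MD index, and (when a
    rarefaction depth is given) the rarefaction medians of both.

    Samples shallower than the rarefaction depth get NaN medians.  The
    rarefaction stream is derived from ``(seed, "rarefaction", sample
    id)`` so per-sample results do not depend on sample order.
    """
    labels = classify_taxa(genus_counts.taxon_lineages, membership)
    rows = []
    values = genus_counts.data.to_numpy()
    for i, sid in enumerate(genus_counts.sample_ids):
        vec = values[i]
        row = {
            "sample_id": sid,
            "depth": float(vec.sum()),
            "shannon": shannon(vec, log_base),
            "md_index": md_index(vec, labels, pseudocount),
        }
        if rarefaction_depth is not None:
            if vec.sum() >= rarefaction_depth:
                rng = stage_rng(seed, f"rarefaction/{sid}")
                row["rarefied_shannon_median"] = rarefaction_median_metric(
                    vec, rarefaction_depth, rarefaction_reps, "shannon", rng,
                    log_base=log_base)
                rng = stage_rng(seed, f"rarefaction-md/{sid}")
                row["rarefied_md_median"] = rarefaction_median_metric(
                    vec, rarefaction_depth, rarefaction_reps, "md_index", rng,
                    labels=labels, pseudocount=pseudocount)
            else:
                row["rarefied_shannon_median"] = np.nan
                row["rarefied_md_median"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
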
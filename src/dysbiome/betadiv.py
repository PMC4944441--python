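"""Weighted UniFrac distances and sequential-SS PERMANOVA.

Weighted UniFrac sums, over every branch of a rooted tree, the branch
length times the absolute difference between the fractions of the two
samples' reads descending through that branch (raw form).  The
normalized form divides by the abundance-weighted mean root-to-leaf
depth of the pair, bounding the distance by 1.

PERMANOVA partitions the variance of a distance matrix among ordered
factors: the squared distances are Gower-centered, each term's sum of
squares is the trace of the centered matrix projected onto the span
added by that term (sequential, Type-I), and significance comes from
jointly permuting the factor rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import TaxonTable, ValidationError

__all__ = [
    "weighted_unifrac",
    "distance_matrix",
    "DistanceMatrix",
    "permanova",
    "PermanovaResult",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValidationError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def _tree_arrays(tree: TreeNode, taxa: list[str]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a rooted tree for vectorized UniFrac.

    Returns (lengths, leaf_membership, leaf_depths): for each non-root
    branch its length and a boolean row marking which taxa descend
    through it, plus each taxon's root-to-leaf depth.
    """
    taxon_pos = {name: i for i, name in enumerate(taxa)}
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValidationError(
            f"taxa absent from the tree: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    nodes = [nd for nd in tree.traverse(include_self=False)]
    lengths = np.array([nd.length for nd in nodes], dtype=float)
    membership = np.zeros((len(nodes), len(taxa)), dtype=bool)
    for k, nd in enumerate(nodes):
        for tip in ([nd] if nd.is_tip() else nd.tips()):
            j = taxon_pos.get(tip.name)
            if j is not None:
                membership[k, j] = True
    depths = membership.T.astype(float) @ lengths
    return lengths, membership, depths


def weighted_unifrac(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    tree: TreeNode,
    taxa: list[str],
    normalized: bool = False,
) -> float:
    """Weighted UniFrac distance between two abundance vectors whose
    entries map onto the tree leaves named in ``taxa``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("negative abundances")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValidationError("zero-sum sample")
    lengths, membership, depths = _tree_arrays(tree, taxa)
    pa = a / a.sum()
    pb = b / b.sum()
    frac_a = membership @ pa
    frac_b = membership @ pb
    raw = float(lengths @ np.abs(frac_a - frac_b))
    if not normalized:
        return raw
    scale = float(depths @ (pa + pb))
    return raw / scale if scale > 0 else 0.0


def distance_matrix(
    table: TaxonTable,
    tree: TreeNode,
    normalized: bool = False,
) -> DistanceMatrix:
    """All pairwise weighted UniFrac distances of a table's samples."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    lengths, membership, depths = _tree_arrays(tree, table.taxon_lineages)
    values = table.data.to_numpy()
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValidationError(f"zero-sum samples: {bad}")
    P = values / totals[:, None]
    fracs = P @ membership.T              # n_samples x n_branches
    n = table.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(fracs[i + 1:] - fracs[i])
        D[i, i + 1:] = diff @ lengths
    D = D + D.T
    if normalized:
        leaf_depth = P @ depths
        scale = leaf_depth[:, None] + leaf_depth[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(scale > 0, D / scale, 0.0)
        np.fill_diagonal(D, 0.0)
    return DistanceMatrix(table.sample_ids, D)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: list[str]
    df: np.ndarray
    sums_of_squares: np.ndarray
    r_squared: np.ndarray
    pseudo_f: np.ndarray
    p_values: np.ndarray | None
    df_residual: int
    ss_residual: float
    ss_total: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, term in enumerate(self.terms):
            rows.append({
                "term": term,
                "df": int(self.df[k]),
                "sum_of_squares": self.sums_of_squares[k],
                "r_squared": self.r_squared[k],
                "pseudo_f": self.pseudo_f[k],
                "p": (np.nan if self.p_values is None else self.p_values[k]),
            })
        rows.append({
            "term": "residual",
            "df": self.df_residual,
            "sum_of_squares": self.ss_residual,
            "r_squared": self.ss_residual / self.ss_total,
            "pseudo_f": np.nan,
            "p": np.nan,
        })
        return pd.DataFrame(rows)


def _factor_design(labels: np.ndarray) -> np.ndarray:
    """Full-rank indicator columns for a factor (reference level dropped),
    or the numeric column itself for a numeric factor."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "fiu" and np.unique(labels).size > 8:
        return labels.reshape(-1, 1).astype(float)
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValidationError("constant factor has no between-group df")
    return (labels[:, None] == levels[1:][None, :]).astype(float)


def _hat(Z: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    keep = diag > (diag.max() * 1e-10 if diag.size else 0)
    q = q[:, keep]
    return q @ q.T


def permanova(
    dist: DistanceMatrix,
    factors: dict[str, np.ndarray],
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA of a distance matrix.

    ``factors`` maps term name to a per-sample label array; terms enter
    in dict order, and each term's SS is the variance it explains
    beyond the terms before it.  Pseudo-F uses the residual mean square
    of the full model.  Permutation p-values jointly permute the factor
    rows and use the add-one convention
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    Pass ``n_permutations=0`` to skip p-values.
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise ValidationError("PERMANOVA needs at least 3 samples")
    for name, labels in factors.items():
        if len(labels) != n:
            raise ValidationError(f"factor {name!r} length mismatch")
    terms = list(factors)
    designs = [_factor_design(np.asarray(factors[t])) for t in terms]

    D2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    ss_total = float(np.trace(G))

    # sequential hat matrices: intercept, then cumulative factor spans
    hats = [np.ones((n, n)) / n]
    dfs = []
    Z = np.ones((n, 1))
    for design in designs:
        Z = np.hstack([Z, design])
        H = _hat(Z)
        dfs.append(int(round(np.trace(H) - np.trace(hats[-1]))))
        hats.append(H)
    df_model = int(round(np.trace(hats[-1]))) - 1
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    deltas = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]

    def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(d * Gm)) for d in deltas])
        ss_resid = float(np.sum(resid_proj * Gm))
        return ss_terms, ss_resid

    ss_terms, ss_resid = stats_for(G)
    dfs_arr = np.array(dfs, dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_terms / dfs_arr) / (ss_resid / df_resid)
    r2 = ss_terms / ss_total

    p_values = None
    if n_permutations >= 1:
        if rng is None:
            rng = np.random.default_rng()
        exceed = np.zeros(len(terms), dtype=int)
        # tolerance keeps permutations that recreate the observed
        # partition (F identical up to round-off) counted as ties
        tol = 1e-8 * np.maximum(1.0, np.abs(f_obs))
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            # permuting factor rows jointly == permuting G rows/cols inversely
            Gp = G[np.ix_(perm, perm)]
            ss_t, ss_r = stats_for(Gp)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (ss_t / dfs_arr) / (ss_r / df_resid)
            exceed += f_p >= f_obs - tol
        p_values = (1 + exceed) / (1 + n_permutations)

    return PermanovaResult(
        terms=terms, df=dfs_arr, sums_of_squares=ss_terms,
        r_squared=r2, pseudo_f=f_obs, p_values=p_values,
        df_residual=df_resid, ss_residual=ss_resid, ss_total=ss_total,
        n_permutations=n_permutations,
    )
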
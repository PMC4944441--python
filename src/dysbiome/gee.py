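"""Weighted linear GEE with independence working correlation and
cluster-robust (sandwich) inference.

With an independence working correlation and identity link, the GEE
point estimate is the weighted-least-squares solution of
``sum_i X_i' W_i (y_i - X_i beta) = 0`` over clusters i; the robust
covariance is the sandwich ``B^-1 M B^-1`` with bread
``B = sum_i X_i' W_i X_i`` and meat
``M = sum_i X_i' W_i e_i e_i' W_i X_i``.  Observations are weighted by
the inverse of their subject's observation count, so densely sampled
subjects do not dominate.  Coefficients are tested with two-sided Wald
chi-square(1) statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE_GROUPS, CohortMetadata, TaxonTable, ValidationError

log = logging.getLogger("dysbiome")

__all__ = [
    "observation_weights",
    "fit_gee",
    "wald_test",
    "GEEFit",
    "GEEModelSpec",
    "model_suite",
    "genus_screen",
    "bonferroni_threshold",
]


def observation_weights(cluster_ids: np.ndarray) -> np.ndarray:
    """Inverse-cluster-size weights: each observation gets 1/(size of
    its cluster), so every cluster's weights sum to 1."""
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.size == 0:
        raise ValidationError("empty cluster vector")
    _, inverse, counts = np.unique(cluster_ids, return_inverse=True,
                                   return_counts=True)
    return 1.0 / counts[inverse]


@dataclass
class GEEFit:
    """One fitted GEE model: coefficients, sandwich covariance, and
    per-coefficient Wald tests."""

    beta: np.ndarray
    robust_cov: np.ndarray
    names: list[str]
    n_obs: int
    n_clusters: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    @property
    def wald_chi2(self) -> np.ndarray:
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.beta / se, np.inf * np.sign(self.beta))
        chi2 = z ** 2
        chi2[np.asarray(self.beta) == 0] = 0.0
        return chi2

    @property
    def p_values(self) -> np.ndarray:
        return stats.chi2.sf(self.wald_chi2, df=1)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.se
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names,
            "beta": self.beta,
            "se": self.se,
            "chi2": self.wald_chi2,
            "p": self.p_values,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        })


def fit_gee(
    X: np.ndarray,
    y: np.ndarray,
    cluster_ids: np.ndarray,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
) -> GEEFit:
    """Fit the weighted independence-GEE linear model.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column yourself or
        use the model-suite helpers).
    y : (n,) response.
    cluster_ids : (n,) subject labels defining the clusters.
    weights : optional per-observation weights; defaults to
        inverse-cluster-size weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    n, p = X.shape
    if y.shape[0] != n or cluster_ids.shape[0] != n:
        raise ValidationError("X, y and cluster_ids must align")
    if weights is None:
        weights = observation_weights(cluster_ids)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValidationError("weights must be positive")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    clusters, cluster_idx = np.unique(cluster_ids, return_inverse=True)
    n_clusters = clusters.size
    if n_clusters < 2:
        raise ValidationError(
            "sandwich covariance undefined with a single cluster")
    if n_clusters < p:
        log.warning("fewer clusters (%d) than parameters (%d): robust SEs "
                    "may be unstable", n_clusters, p)

    Xw = X * w[:, None]
    bread = X.T @ Xw  # sum_i X_i' W_i X_i
    sv = np.linalg.svd(bread, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-12:
        aliased = _aliased_columns(X * np.sqrt(w)[:, None], names)
        raise ValidationError(f"design matrix rank deficient; aliased "
                              f"columns: {aliased}")
    beta = np.linalg.solve(bread, Xw.T @ y)
    resid = y - X @ beta

    # meat: per-cluster score outer products, sum_i g_i g_i'
    g = Xw * resid[:, None]                      # per-observation scores
    scores = np.zeros((n_clusters, p))
    np.add.at(scores, cluster_idx, g)
    meat = scores.T @ scores

    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    cov = (cov + cov.T) / 2.0
    return GEEFit(beta=beta, robust_cov=cov, names=list(names),
                  n_obs=n, n_clusters=n_clusters)


def _aliased_columns(Xw: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in a rank deficiency via pivoted QR."""
    _, r = np.linalg.qr(Xw)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    return [names[j] for j in range(len(names))
            if j < diag.size and diag[j] <= tol]


def wald_test(fit: GEEFit, coefficient: int) -> tuple[float, float]:
    """Two-sided Wald test of one coefficient: chi2 = (beta/se)^2,
    p = upper tail of chi-square with 1 df.

    A zero robust SE (degenerate, e.g. an exact linear fit) reports
    p = 0 with a warning unless beta is also 0 (then chi2=0, p=1).
    """
    beta = float(fit.beta[coefficient])
    se = float(fit.se[coefficient])
    if se == 0.0:
        if beta == 0.0:
            return 0.0, 1.0
        log.warning("zero robust SE for %s: degenerate Wald test",
                    fit.names[coefficient])
        return float("inf"), 0.0
    chi2 = (beta / se) ** 2
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# model suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GEEModelSpec:
    """Declarative description of one model in the suite.

    ``covariates`` is an ordered tuple of term names drawn from:
    ``status`` (case vs control), ``diagnosis`` (CD and UC indicators
    vs pooled controls), ``uc_vs_cd`` (UC indicator, cases only),
    ``time`` (days since enrollment), ``diagnosis:time`` / ``status:time``
    interactions, or any numeric metadata/metric column name (e.g.
    ``md_index`` for marker-on-marker models).  An intercept is always
    included.
    """

    name: str
    response: str
    covariates: tuple[str, ...]
    subset: str = "all"  # all | cases
    weighting: str = "inverse_cluster_size"  # or "unweighted"


def _build_design(df: pd.DataFrame, covariates: tuple[str, ...]
                  ) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    is_case = df["group"].isin(CASE_GROUPS).to_numpy().astype(float)
    cd = (df["group"] == "CD").to_numpy().astype(float)
    uc = (df["group"] == "UC").to_numpy().astype(float)
    t = df["time_days"].to_numpy(dtype=float)
    nonresp = (df["responder"] == "non_responder").to_numpy().astype(float)
    for term in covariates:
        if term == "status":
            cols.append(is_case); names.append("case")
        elif term == "diagnosis":
            cols.append(cd); names.append("CD")
            cols.append(uc); names.append("UC")
        elif term == "uc_vs_cd":
            cols.append(uc); names.append("UC_vs_CD")
        elif term == "nonresponder":
            cols.append(nonresp); names.append("non_responder")
        elif term == "time":
            cols.append(t); names.append("time_days")
        elif term == "status:time":
            cols.append(is_case * t); names.append("case:time_days")
        elif term == "diagnosis:time":
            cols.append(cd * t); names.append("CD:time_days")
            cols.append(uc * t); names.append("UC:time_days")
        elif term == "nonresponder:time":
            cols.append(nonresp * t); names.append("non_responder:time_days")
        elif term in df.columns:
            cols.append(df[term].to_numpy(dtype=float)); names.append(term)
        else:
            raise ValidationError(f"unknown model term {term!r}")
    return np.column_stack(cols), names


def _fit_spec(df: pd.DataFrame, spec: GEEModelSpec) -> GEEFit | None:
    data = df
    if spec.subset == "cases":
        data = df[df["group"].isin(CASE_GROUPS)]
    elif spec.subset == "pretreatment_cases":
        data = df[df["group"].isin(CASE_GROUPS) & df["pretreatment_flag"]]
    if spec.response not in data.columns:
        raise ValidationError(f"model {spec.name}: missing response column "
                              f"{spec.response!r}")
    X, names = _build_design(data, spec.covariates)
    y = data[spec.response].to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("model %s: dropped %d observations with missing values",
                 spec.name, dropped)
    data = data[keep]
    X, y = X[keep], y[keep]
    if len(data) == 0:
        log.warning("model %s: no usable observations, skipped", spec.name)
        return None
    # drop indicator columns for empty groups rather than failing
    nonconst = [j for j in range(X.shape[1])
                if j == 0 or not np.allclose(X[:, j], X[0, j])]
    if len(nonconst) < X.shape[1]:
        skipped = [names[j] for j in range(X.shape[1]) if j not in nonconst]
        log.warning("model %s: constant terms %s dropped (empty group?)",
                    spec.name, skipped)
        X = X[:, nonconst]
        names = [names[j] for j in nonconst]
    clusters = data["subject_id"].to_numpy()
    if np.unique(clusters).size < 2:
        log.warning("model %s: fewer than 2 clusters, skipped", spec.name)
        return None
    weights = (None if spec.weighting == "inverse_cluster_size"
               else np.ones(len(y)))
    return fit_gee(X, y, clusters, weights, names)


DEFAULT_MODEL_SUITE: tuple[GEEModelSpec, ...] = (
    # average group differences over the whole study
    GEEModelSpec("calprotectin_avg", "calprotectin", ("diagnosis",)),
    GEEModelSpec("shannon_avg", "shannon", ("diagnosis",)),
    GEEModelSpec("md_avg", "md_index", ("diagnosis",)),
    # baseline contrasts: group + time (time since first sample as covariate)
    GEEModelSpec("calprotectin_baseline", "calprotectin", ("diagnosis", "time")),
    GEEModelSpec("shannon_baseline", "shannon", ("diagnosis", "time")),
    GEEModelSpec("md_baseline", "md_index", ("diagnosis", "time")),
    # time trends with diagnosis interactions
    GEEModelSpec("calprotectin_trend", "calprotectin",
                 ("diagnosis", "time", "diagnosis:time")),
    GEEModelSpec("shannon_trend", "shannon",
                 ("diagnosis", "time", "diagnosis:time")),
    GEEModelSpec("md_trend", "md_index",
                 ("diagnosis", "time", "diagnosis:time")),
    # marker-on-marker models
    GEEModelSpec("calprotectin_on_md", "calprotectin", ("md_index",)),
    GEEModelSpec("calprotectin_on_md_cases", "calprotectin", ("md_index",),
                 subset="cases"),
    GEEModelSpec("calprotectin_on_shannon", "calprotectin", ("shannon",)),
    GEEModelSpec("calprotectin_on_activity", "calprotectin",
                 ("activity_index",), subset="cases"),
    GEEModelSpec("activity_on_md", "activity_index", ("md_index",),
                 subset="cases"),
)


def model_suite(
    metrics: pd.DataFrame,
    metadata: CohortMetadata,
    specs: tuple[GEEModelSpec, ...] = DEFAULT_MODEL_SUITE,
) -> pd.DataFrame:
    """Fit the suite of marker models and return one row per
    model x coefficient.

    ``metrics`` must carry ``sample_id`` plus the per-sample metric
    columns (``shannon``, ``md_index``, ...); it is joined to the
    metadata on sample ID.
    """
    df = metadata.data.merge(metrics, on="sample_id", how="inner",
                             validate="one_to_one")
    rows = []
    for spec in specs:
        fit = _fit_spec(df, spec)
        if fit is None:
            continue
        frame = fit.to_frame()
        frame.insert(0, "model", spec.name)
        rows.append(frame)
    if not rows:
        raise ValidationError("no model in the suite could be fitted")
    return pd.concat(rows, ignore_index=True)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def genus_screen(
    freq_table: TaxonTable,
    metadata: CohortMetadata,
    contrast: str = "case_vs_control",
    alpha: float = 0.05,
    include_time: bool = True,
    transform: str = "identity",
    pseudocount: float = 1e-5,
) -> pd.DataFrame:
    """Genus-by-genus GEE screen of abundance against a group contrast.

    For each genus, abundance is modeled as contrast indicator
    (+ time for baseline-style contrasts) with inverse-cluster-size
    weights and sandwich SEs.  Returns per-genus beta, direction,
    nominal p (flagged at p <= 0.05), and a Bonferroni flag at
    ``alpha / G`` where G is the number of genera tested.

    ``contrast``: ``case_vs_control`` over all samples, or
    ``nonresponder_vs_responder`` over case samples only.
    ``transform``: ``identity``, ``arcsin_sqrt`` or ``log_pseudocount``
    applied to the frequency response.
    """
    md = metadata.aligned_to(freq_table)
    df = md.data
    if contrast == "case_vs_control":
        keep = np.ones(len(df), dtype=bool)
        indicator = df["group"].isin(CASE_GROUPS).to_numpy().astype(float)
        label = "case"
    elif contrast == "nonresponder_vs_responder":
        keep = df["group"].isin(CASE_GROUPS).to_numpy()
        indicator = (df["responder"] == "non_responder").to_numpy().astype(float)
        label = "non_responder"
    else:
        raise ValidationError(f"unknown contrast {contrast!r}")

    df = df[keep]
    indicator = indicator[keep]
    values = freq_table.data.to_numpy()[keep]
    if transform == "arcsin_sqrt":
        values = np.arcsin(np.sqrt(np.clip(values, 0, 1)))
    elif transform == "log_pseudocount":
        values = np.log10(values + pseudocount)
    elif transform != "identity":
        raise ValidationError(f"unknown transform {transform!r}")

    t = df["time_days"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), indicator]
    names = ["intercept", label]
    if include_time:
        cols.append(t)
        names.append("time_days")
    X = np.column_stack(cols)
    clusters = df["subject_id"].to_numpy()
    weights = observation_weights(clusters)

    n_tested = freq_table.n_taxa
    bonf = bonferroni_threshold(alpha, n_tested)
    rows = []
    for j, lineage in enumerate(freq_table.taxon_lineages):
        fit = fit_gee(X, values[:, j], clusters, weights, names)
        beta = float(fit.beta[1])
        _, p = wald_test(fit, 1)
        rows.append({
            "taxon": lineage,
            "beta": beta,
            "se": float(fit.se[1]),
            "direction": "up" if beta > 0 else ("down" if beta < 0 else "flat"),
            "p": p,
            "nominal_significant": p <= 0.05,
            "bonferroni_significant": p < bonf,
        })
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = bonf
    out.attrs["n_tested"] = n_tested
    out.attrs["contrast"] = contrast
    return out
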
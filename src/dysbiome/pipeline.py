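"""End-to-end pipeline: from a genus/OTU count table, metadata and
optional tree to per-sample metrics, GEE tables, the genus screen,
PERMANOVA, and the treatment-response forest report.

Every stage derives its random stream from ``(config.seed, stage
name)``, so reruns with the same inputs and seed are byte-identical
and stage order never changes results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .betadiv import distance_matrix, permanova
from .containers import (
    CASE_GROUPS,
    CohortMetadata,
    RunConfig,
    TaxonTable,
    ValidationError,
    stage_rng,
    stage_seed,
)
from .diversity import sample_metrics
from .forest import (
    ForestConfig,
    gini_importance,
    grow_forest,
    oob_report,
    permutation_significance,
    precision_recall,
    roc_auc,
)
from .gee import genus_screen, model_suite
from .io import write_taxon_table
from .taxa import (
    collapse_to_genus,
    exclude_low_depth_samples,
    prevalence_filter,
    prevalence_report,
    relative_abundance,
)

log = logging.getLogger("dysbiome")


def pretreatment_selection(metadata: CohortMetadata) -> pd.DataFrame:
    """One pretreatment sample per case subject: the flagged sample,
    or the earliest flagged sample when a subject carries several."""
    df = metadata.data
    pre = df[df["group"].isin(CASE_GROUPS) & df["pretreatment_flag"]]
    picked = (pre.sort_values(["subject_id", "time_days"])
              .groupby("subject_id", as_index=False).first())
    extra = len(pre) - len(picked)
    if extra:
        log.info("pretreatment selection: %d extra flagged samples ignored "
                 "(earliest kept per subject)", extra)
    return picked


def run_pipeline(
    table: TaxonTable,
    metadata: CohortMetadata,
    tree,
    config: RunConfig,
    out_dir: str | Path,
    rarefaction: bool = True,
) -> dict:
    """Run every stage and write the results directory.

    Returns the manifest dictionary.  ``tree`` may be None to skip the
    UniFrac/PERMANOVA stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name, **info):
        log.info("stage %s: %s", name, info)
        manifest["stages"][name] = info

    # ---- depth filter + genus collapse ------------------------------
    try:
        filtered = exclude_low_depth_samples(table, config.min_reads)
    except ValidationError as exc:
        raise ValidationError(f"stage depth_filter failed: {exc}") from exc
    stage("depth_filter", n_in=table.n_samples, n_out=filtered.n_samples,
          min_reads=config.min_reads)
    genus = collapse_to_genus(filtered)
    stage("genus_collapse", n_taxa_in=filtered.n_taxa, n_taxa_out=genus.n_taxa)
    metadata = metadata.subset(genus.sample_ids)

    # ---- per-sample metrics -----------------------------------------
    metrics = sample_metrics(
        genus,
        log_base=config.shannon_log_base,
        pseudocount=config.pseudocount,
        rarefaction_depth=config.rarefaction_depth if rarefaction else None,
        rarefaction_reps=config.rarefaction_reps,
        seed=config.seed,
    )
    metrics.to_csv(out / "sample_metrics.tsv", sep="\t", index=False,
                   float_format="%.10g")
    stage("metrics", n_samples=len(metrics),
          rarefaction_reps=config.rarefaction_reps if rarefaction else 0)

    # ---- frequencies + prevalence filter ----------------------------
    freqs = relative_abundance(genus)
    report = prevalence_report(freqs, config.prevalence_threshold)
    report.to_csv(out / "prevalence_filter.tsv", sep="\t", index=False,
                  float_format="%.10g")
    screened = prevalence_filter(freqs, config.prevalence_threshold)
    write_taxon_table(screened, out / "genus_frequencies_filtered.tsv")
    stage("prevalence_filter", threshold=config.prevalence_threshold,
          n_taxa_in=freqs.n_taxa, n_taxa_out=screened.n_taxa)

    # ---- GEE model suite + genus screens ----------------------------
    suite = model_suite(metrics, metadata)
    suite.to_csv(out / "gee_models.tsv", sep="\t", index=False,
                 float_format="%.10g")
    stage("gee", n_models=suite["model"].nunique())

    screens = {
        "screen_case_control.tsv": genus_screen(
            screened, metadata, "case_vs_control", include_time=True,
            pseudocount=config.pseudocount),
        "screen_responder.tsv": genus_screen(
            screened, metadata, "nonresponder_vs_responder",
            include_time=True, pseudocount=config.pseudocount),
        "screen_responder_no_time.tsv": genus_screen(
            screened, metadata, "nonresponder_vs_responder",
            include_time=False, pseudocount=config.pseudocount),
    }
    for fname, frame in screens.items():
        frame.to_csv(out / fname, sep="\t", index=False, float_format="%.10g")
    stage("genus_screen", n_genera=screened.n_taxa,
          bonferroni_threshold=screens["screen_case_control.tsv"]
          .attrs["bonferroni_threshold"])

    # ---- pretreatment subset ----------------------------------------
    picked = pretreatment_selection(metadata)
    pre_ids = picked["sample_id"].tolist()
    y = (picked["responder"] == "responder").to_numpy().astype(int)

    # ---- PERMANOVA on weighted UniFrac ------------------------------
    if tree is not None and len(pre_ids) >= 3:
        pre_freqs = TaxonTable(freqs.data.loc[pre_ids],
                               value_kind="frequencies")
        dm = distance_matrix(pre_freqs, tree,
                             normalized=config.unifrac_normalized)
        dm.to_frame().to_csv(out / "unifrac_pretreatment.tsv", sep="\t",
                             float_format="%.10g")
        factors = {
            "responder": picked["responder"].to_numpy(),
            "subtype": picked["group"].to_numpy(),
        }
        res = permanova(dm, factors,
                        n_permutations=config.n_permutations,
                        rng=stage_rng(config.seed, "permanova"))
        res.to_frame().to_csv(out / "permanova.tsv", sep="\t", index=False,
                              float_format="%.10g")
        stage("permanova", n_samples=len(pre_ids),
              n_permutations=config.n_permutations)

    # ---- random forest ----------------------------------------------
    forest_out = None
    if len(pre_ids) >= 4 and len(np.unique(y)) == 2:
        X = screened.data.loc[pre_ids].to_numpy()
        names = screened.taxon_lineages
        fc = ForestConfig(n_trees=config.n_trees, mtry=config.mtry,
                          seed=stage_seed(config.seed, "forest"))
        model = grow_forest(X, y, fc, feature_names=names)
        rep = oob_report(model, y)
        usable = np.isfinite(model.oob_votes)
        roc_points, auc = roc_auc(model.oob_votes[usable], y[usable])
        pr_points = precision_recall(model.oob_votes[usable], y[usable])
        pd.DataFrame(roc_points, columns=["fpr", "tpr"]).to_csv(
            out / "roc_points.tsv", sep="\t", index=False,
            float_format="%.10g")
        pd.DataFrame(pr_points, columns=["recall", "precision"]).to_csv(
            out / "pr_points.tsv", sep="\t", index=False,
            float_format="%.10g")
        imp = gini_importance(model)
        pd.DataFrame(imp, columns=["taxon", "importance"]).to_csv(
            out / "importance.tsv", sep="\t", index=False,
            float_format="%.10g")

        perm_cfg = ForestConfig(n_trees=config.n_permutation_trees,
                                mtry=config.mtry, seed=fc.seed)
        if config.n_permutations >= 1:
            p_acc = permutation_significance(
                X, y, "accuracy", rep.accuracy, config.n_permutations,
                perm_cfg, stage_rng(config.seed, "forest-perm-acc"))
            p_auc = permutation_significance(
                X, y, "auc", auc, config.n_permutations,
                perm_cfg, stage_rng(config.seed, "forest-perm-auc"))
        else:
            p_acc = p_auc = "not computed"
        forest_out = {
            "n_samples": int(len(pre_ids)),
            "n_responders": int(y.sum()),
            "n_nonresponders": int(len(y) - y.sum()),
            "n_trees": config.n_trees,
            "mtry": model.mtry_used,
            "confusion": rep.confusion.tolist(),
            "accuracy": rep.accuracy,
            "per_class_error": {
                "non_responder": rep.per_class_error[0],
                "responder": rep.per_class_error[1],
            },
            "auc": auc,
            "permutation_p_accuracy": p_acc,
            "permutation_p_auc": p_auc,
            "n_permutations": config.n_permutations,
            "n_permutation_trees": config.n_permutation_trees,
            "top_importance": imp[:15],
            "seed": fc.seed,
        }
        with open(out / "forest_report.json", "w") as fh:
            json.dump(forest_out, fh, indent=2)
        stage("forest", accuracy=rep.accuracy, auc=auc)
    else:
        log.warning("forest stage skipped: not enough pretreatment samples "
                    "with both outcomes")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
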
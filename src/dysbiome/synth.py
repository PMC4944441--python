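"""Synthetic longitudinal IBD cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a
pediatric cohort of pooled controls, Crohn's disease (CD) and
ulcerative colitis (UC) patients sampled repeatedly over ~8 months,
with genus-level count tables, fecal calprotectin, clinical activity
scores, and known ground truth for every effect.

The composition model is logistic-normal/softmax over a fixed genus
panel: each sample's genus log-abundances are a panel baseline plus
disease offsets, responder offsets, a per-subject random effect and
per-visit noise; counts are multinomial at a lognormal sequencing
depth floored at the rarefaction depth.  Disease offsets act uniformly
(in log space) on the increased-in-CD families, which makes the
group contrast of the MD index exactly the configured offset on the
log10 scale.  Calprotectin is linear in each sample's realized MD
index, so the marker-on-marker GEE has a well-defined true slope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CohortMetadata, TaxonTable, ValidationError, stage_rng
from .diversity import DEFAULT_MEMBERSHIP, classify_taxa, md_index

__all__ = [
    "CohortSimConfig",
    "GroundTruth",
    "default_panel",
    "simulate_cohort",
    "simulate_pretreatment_classification",
    "star_tree",
]

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# genus panel
# ---------------------------------------------------------------------------

_L = "k__Bacteria;p__{p};c__{c};o__{o};f__{f};g__{g}"


def _lineage(p, c, o, f, g):
    return _L.format(p=p, c=c, o=o, f=f, g=g)


def _bacteroidales(f, g):
    return _lineage("Bacteroidetes", "Bacteroidia", "Bacteroidales", f, g)


def _clostridiales(f, g):
    return _lineage("Firmicutes", "Clostridia", "Clostridiales", f, g)


# (lineage, control relative abundance, non-responder log-fold offset)
# Non-responder effects mirror the reported pretreatment signature:
# Lachnospiraceae-type genera (Coprococcus, Roseburia, Lachnospira,
# Blautia, Dorea), Faecalibacterium and Adlercreutzia reduced in
# non-responders; Akkermansia, Veillonella, Dialister, Fusobacterium
# and Enterobacteriaceae increased.
_NAMED_PANEL: list[tuple[str, float, float]] = [
    # Bacteroidales (decreased-in-CD)
    (_bacteroidales("Bacteroidaceae", "Bacteroides"), 0.130, 0.0),
    (_bacteroidales("Prevotellaceae", "Prevotella"), 0.040, 0.0),
    (_bacteroidales("Porphyromonadaceae", "Parabacteroides"), 0.030, 0.0),
    (_bacteroidales("Rikenellaceae", ""), 0.012, 0.0),
    # Clostridiales (decreased-in-CD)
    (_clostridiales("Ruminococcaceae", "Faecalibacterium"), 0.065, -0.6),
    (_clostridiales("Lachnospiraceae", "Coprococcus"), 0.030, -0.9),
    (_clostridiales("Lachnospiraceae", "Blautia"), 0.040, -0.6),
    (_clostridiales("Lachnospiraceae", "Roseburia"), 0.030, -0.7),
    (_clostridiales("Lachnospiraceae", "Lachnospira"), 0.020, -0.7),
    (_clostridiales("Lachnospiraceae", "Dorea"), 0.015, -0.5),
    (_clostridiales("Lachnospiraceae", ""), 0.030, -0.7),
    (_clostridiales("Ruminococcaceae", "Ruminococcus"), 0.040, 0.0),
    (_clostridiales("Ruminococcaceae", "Oscillospira"), 0.020, 0.0),
    (_clostridiales("Ruminococcaceae", ""), 0.030, 0.0),
    (_clostridiales("Clostridiaceae", "Clostridium"), 0.010, 0.0),
    # other decreased-in-CD families
    (_lineage("Firmicutes", "Erysipelotrichi", "Erysipelotrichales",
              "Erysipelotrichaceae", "[Eubacterium]"), 0.006, 0.0),
    (_lineage("Actinobacteria", "Actinobacteria", "Bifidobacteriales",
              "Bifidobacteriaceae", "Bifidobacterium"), 0.030, 0.0),
    # increased-in-CD families
    (_lineage("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
              "Enterobacteriaceae", ""), 0.0036, 0.5),
    (_lineage("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
              "Enterobacteriaceae", "Escherichia"), 0.0022, 0.5),
    (_lineage("Proteobacteria", "Gammaproteobacteria", "Pasteurellales",
              "Pasteurellaceae", "Haemophilus"), 0.0011, 0.0),
    (_lineage("Fusobacteria", "Fusobacteriia", "Fusobacteriales",
              "Fusobacteriaceae", "Fusobacterium"), 0.00055, 0.9),
    (_lineage("Proteobacteria", "Betaproteobacteria", "Neisseriales",
              "Neisseriaceae", "Neisseria"), 0.00055, 0.0),
    (_clostridiales("Veillonellaceae", "Veillonella"), 0.0022, 0.9),
    (_clostridiales("Veillonellaceae", "Dialister"), 0.0016, 0.8),
    (_lineage("Firmicutes", "Bacilli", "Gemellales", "Gemellaceae",
              "Gemella"), 0.00055, 0.0),
    # neither set
    (_lineage("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales",
              "Verrucomicrobiaceae", "Akkermansia"), 0.020, 1.0),
    (_lineage("Actinobacteria", "Coriobacteriia", "Coriobacteriales",
              "Coriobacteriaceae", "Adlercreutzia"), 0.004, -0.8),
    (_lineage("Actinobacteria", "Coriobacteriia", "Coriobacteriales",
              "Coriobacteriaceae", "Collinsella"), 0.010, 0.0),
    (_lineage("Firmicutes", "Bacilli", "Lactobacillales",
              "Lactobacillaceae", "Lactobacillus"), 0.005, 0.0),
    (_lineage("Firmicutes", "Bacilli", "Lactobacillales",
              "Streptococcaceae", "Streptococcus"), 0.008, 0.0),
    (_lineage("Firmicutes", "Bacilli", "Lactobacillales",
              "Enterococcaceae", "Enterococcus"), 0.002, 0.0),
    (_lineage("Proteobacteria", "Betaproteobacteria", "Burkholderiales",
              "Alcaligenaceae", "Sutterella"), 0.010, 0.0),
    (_lineage("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales",
              "Desulfovibrionaceae", "Desulfovibrio"), 0.005, 0.0),
    (_lineage("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales",
              "Desulfovibrionaceae", "Bilophila"), 0.004, 0.0),
    (_lineage("Euryarchaeota", "Methanobacteria", "Methanobacteriales",
              "Methanobacteriaceae", "Methanobrevibacter"), 0.003, 0.0),
]

# filler genera keep the panel's richness realistic (and Shannon near
# its target); they cycle through common gut families
_FILLER_FAMILIES = [
    ("Lachnospiraceae", _clostridiales),
    ("Ruminococcaceae", _clostridiales),
    ("Clostridiaceae", _clostridiales),
    ("Christensenellaceae", _clostridiales),
    ("Bacteroidaceae", _bacteroidales),
    ("Porphyromonadaceae", _bacteroidales),
    ("Rikenellaceae", _bacteroidales),
    (
        "Coriobacteriaceae",
        lambda f, g: _lineage("Actinobacteria", "Coriobacteriia",
                              "Coriobacteriales", f, g),
    ),
]

N_FILLER = 130
_FILLER_TOP = 0.010       # most abundant filler genus
_FILLER_RATIO = 0.978     # geometric decay across the filler tail


def default_panel() -> pd.DataFrame:
    """The default genus panel: lineage, baseline log-abundance, and
    the non-responder log-fold offset per genus."""
    rows = []
    for lineage, ab, nr in _NAMED_PANEL:
        rows.append({"lineage": lineage, "base": math.log(ab),
                     "nonresponder_offset": nr})
    ab = _FILLER_TOP
    for i in range(N_FILLER):
        fam, maker = _FILLER_FAMILIES[i % len(_FILLER_FAMILIES)]
        lineage = maker(fam, f"GenusF{i:03d}")
        rows.append({"lineage": lineage, "base": math.log(ab),
                     "nonresponder_offset": 0.0})
        ab *= _FILLER_RATIO
    panel = pd.DataFrame(rows)
    panel["md_label"] = classify_taxa(panel["lineage"].tolist(),
                                      DEFAULT_MEMBERSHIP)
    return panel


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Study-condition parameters of the simulated cohort.

    Group sizes default to the template cohort: 10 controls (6
    familial + 4 unrelated), 15 CD (6 responders + 9 non-responders),
    4 UC (all non-responders).  Visit counts are uniform on 1..12
    (median ~6) over a 240-day follow-up; depths are lognormal with
    median ~66,000 reads floored at 3,155.  MD-index group offsets
    default to +0.86 (CD) and +1.75 (UC) over a control mean near
    -1.85; calprotectin is 42 ug/g at the control MD level and rises
    260 ug/g per MD unit.
    """

    n_control_familial: int = 6
    n_control_unrelated: int = 4
    n_cd_responder: int = 6
    n_cd_nonresponder: int = 9
    n_uc_nonresponder: int = 4
    visits_min: int = 1
    visits_max: int = 12
    followup_days: float = 240.0
    depth_log_mean: float = math.log(66000.0)
    depth_log_sd: float = 0.55
    depth_floor: int = 3155
    md_offset_cd: float = 0.86
    md_offset_uc: float = 1.75
    decay_fraction: float = 0.4   # linear fade of disease offsets over follow-up
    subject_sd: float = 0.4       # per-genus subject random effect (log scale)
    visit_sd: float = 0.25        # per-genus per-visit noise (log scale)
    responder_effect_scale: float = 1.0
    cal_intercept: float = 42.0
    cal_slope: float = 260.0
    cal_extra_cd: float = 0.0     # direct group offsets beyond the MD link
    cal_extra_uc: float = 0.0
    cal_subject_sd: float = 25.0
    cal_resid_sd: float = 35.0
    cal_distribution: str = "truncated_normal"  # or "lognormal"
    pseudocount: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "visit_sd", "cal_subject_sd",
                     "cal_resid_sd", "depth_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.visits_min < 1 or self.visits_max < self.visits_min:
            raise ValidationError("invalid visit range")
        if self.cal_distribution not in ("truncated_normal", "lognormal"):
            raise ValidationError("unknown calprotectin distribution")

    def with_(self, **kwargs) -> "CohortSimConfig":
        return replace(self, **kwargs)

    def scaled(self, factor: int) -> "CohortSimConfig":
        """Multiply every group size by an integer factor."""
        return self.with_(
            n_control_familial=self.n_control_familial * factor,
            n_control_unrelated=self.n_control_unrelated * factor,
            n_cd_responder=self.n_cd_responder * factor,
            n_cd_nonresponder=self.n_cd_nonresponder * factor,
            n_uc_nonresponder=self.n_uc_nonresponder * factor,
        )


@dataclass
class GroundTruth:
    """Effects the generator built in, for recovery tests."""

    md_offset_cd: float
    md_offset_uc: float
    cal_slope: float
    cal_intercept: float
    cal_extra_cd: float
    cal_extra_uc: float
    md_control_ref: float
    decay_fraction: float
    responder_genera: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _control_reference_md(panel: pd.DataFrame, pseudocount: float) -> float:
    base = np.exp(panel["base"].to_numpy())
    comp = base / base.sum()
    return md_index(comp, panel["md_label"].to_numpy(), pseudocount)


def star_tree(taxa: list[str]) -> TreeNode:
    """A star phylogeny with unit branch lengths over the panel.

    Raw weighted UniFrac on a star tree reduces to the L1 distance
    between compositions, which makes the tree code path analytically
    checkable."""
    root = TreeNode(name="root", length=0.0)
    for name in taxa:
        root.append(TreeNode(name=name, length=1.0))
    return root


def _subject_plan(config: CohortSimConfig) -> list[tuple[str, str, str]]:
    plan = []
    for i in range(config.n_control_familial):
        plan.append((f"F{i + 1:03d}", "control_familial", "not_applicable"))
    for i in range(config.n_control_unrelated):
        plan.append((f"U{i + 1:03d}", "control_unrelated", "not_applicable"))
    for i in range(config.n_cd_responder):
        plan.append((f"CDR{i + 1:03d}", "CD", "responder"))
    for i in range(config.n_cd_nonresponder):
        plan.append((f"CDN{i + 1:03d}", "CD", "non_responder"))
    for i in range(config.n_uc_nonresponder):
        plan.append((f"UCN{i + 1:03d}", "UC", "non_responder"))
    return plan


def simulate_cohort(
    config: CohortSimConfig = CohortSimConfig(),
    panel: pd.DataFrame | None = None,
) -> tuple[TaxonTable, CohortMetadata, GroundTruth, TreeNode]:
    """Simulate a longitudinal cohort.

    Returns the genus count table, the per-sample metadata, the ground
    truth, and a star tree over the panel.
    """
    if panel is None:
        panel = default_panel()
    labels = panel["md_label"].to_numpy()
    if "increased" not in labels or "decreased" not in labels:
        raise ValidationError(
            "panel must contain both MD membership classes, otherwise "
            "the MD index is degenerate")
    base = panel["base"].to_numpy(dtype=float)
    nr_offset = (panel["nonresponder_offset"].to_numpy(dtype=float)
                 * config.responder_effect_scale)
    increased = (labels == "increased").astype(float)
    delta_cd = LN10 * config.md_offset_cd * increased
    delta_uc = LN10 * config.md_offset_uc * increased
    md_ref = _control_reference_md(panel, config.pseudocount)

    rng = stage_rng(config.seed, "simulate_cohort")
    plan = _subject_plan(config)
    n_genera = len(panel)

    count_rows, meta_rows = [], []
    sample_ids = []
    for subject_id, group, responder in plan:
        n_visits = int(rng.integers(config.visits_min, config.visits_max + 1))
        if n_visits == 1:
            times = np.array([0.0])
        else:
            later = np.sort(rng.uniform(14.0, config.followup_days,
                                        n_visits - 1))
            times = np.concatenate([[0.0], later])
        subject_effect = rng.normal(0.0, config.subject_sd, n_genera)
        cal_subject = rng.normal(0.0, config.cal_subject_sd)
        for v, t in enumerate(times):
            decay = 1.0 - config.decay_fraction * t / config.followup_days
            eta = base + subject_effect + rng.normal(0.0, config.visit_sd,
                                                     n_genera)
            if group == "CD":
                eta = eta + delta_cd * decay
            elif group == "UC":
                eta = eta + delta_uc * decay
            if responder == "non_responder":
                eta = eta + nr_offset
            comp = np.exp(eta - eta.max())
            comp /= comp.sum()
            depth = int(max(config.depth_floor,
                            round(rng.lognormal(config.depth_log_mean,
                                                config.depth_log_sd))))
            counts = rng.multinomial(depth, comp)
            md_i = md_index(counts, labels, config.pseudocount)
            linpred = (config.cal_intercept
                       + config.cal_slope * (md_i - md_ref)
                       + (config.cal_extra_cd if group == "CD" else 0.0)
                       + (config.cal_extra_uc if group == "UC" else 0.0))
            if config.cal_distribution == "truncated_normal":
                cal = max(0.0, linpred + cal_subject
                          + rng.normal(0.0, config.cal_resid_sd))
            else:
                sigma = config.cal_resid_sd / max(abs(linpred), 1.0)
                cal = max(linpred, 1.0) * rng.lognormal(0.0, min(sigma, 1.0))
            sid = f"{subject_id}.V{v + 1:02d}"
            sample_ids.append(sid)
            count_rows.append(counts)
            meta_rows.append({
                "sample_id": sid,
                "subject_id": subject_id,
                "group": group,
                "responder": responder,
                "time_days": float(t),
                "calprotectin": cal,
                "activity_index": np.nan,
                "pretreatment_flag": bool(group in ("CD", "UC") and v == 0),
            })

    meta = pd.DataFrame(meta_rows)
    # activity index: noisy monotone transform of the calprotectin rank
    # among case samples
    cases = meta["group"].isin(["CD", "UC"])
    if cases.any():
        pct = meta.loc[cases, "calprotectin"].rank(pct=True)
        noise = rng.normal(0.0, 5.0, int(cases.sum()))
        meta.loc[cases, "activity_index"] = np.clip(
            55.0 * pct.to_numpy() + noise, 0.0, None)

    table = TaxonTable(
        pd.DataFrame(np.array(count_rows, dtype=float), index=sample_ids,
                     columns=panel["lineage"].tolist()),
        value_kind="counts",
    )
    metadata = CohortMetadata(meta)
    truth = GroundTruth(
        md_offset_cd=config.md_offset_cd,
        md_offset_uc=config.md_offset_uc,
        cal_slope=config.cal_slope,
        cal_intercept=config.cal_intercept,
        cal_extra_cd=config.cal_extra_cd,
        cal_extra_uc=config.cal_extra_uc,
        md_control_ref=md_ref,
        decay_fraction=config.decay_fraction,
        responder_genera={
            lin: off for lin, off in zip(panel["lineage"], nr_offset)
            if off != 0.0
        },
    )
    return table, metadata, truth, star_tree(panel["lineage"].tolist())


def simulate_pretreatment_classification(
    config: CohortSimConfig = CohortSimConfig(),
    n_responders: int = 5,
    n_nonresponders: int = 12,
    panel: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """One pretreatment sample per case subject for the classifier.

    Returns a samples-by-genus frequency DataFrame, binary labels
    (1 = responder), and the ground truth.  Responder effects are the
    panel's non-responder offsets; disease offsets are the CD ones
    (subtype is deliberately not distinguished).
    """
    if panel is None:
        panel = default_panel()
    labels = panel["md_label"].to_numpy()
    base = panel["base"].to_numpy(dtype=float)
    nr_offset = (panel["nonresponder_offset"].to_numpy(dtype=float)
                 * config.responder_effect_scale)
    increased = (labels == "increased").astype(float)
    delta = LN10 * config.md_offset_cd * increased

    rng = stage_rng(config.seed, "simulate_pretreatment")
    n = n_responders + n_nonresponders
    y = np.r_[np.ones(n_responders, dtype=int),
              np.zeros(n_nonresponders, dtype=int)]
    rows, ids = [], []
    n_genera = len(panel)
    for i in range(n):
        eta = (base + delta
               + rng.normal(0.0, config.subject_sd, n_genera)
               + rng.normal(0.0, config.visit_sd, n_genera))
        if y[i] == 0:
            eta = eta + nr_offset
        comp = np.exp(eta - eta.max())
        comp /= comp.sum()
        depth = int(max(config.depth_floor,
                        round(rng.lognormal(config.depth_log_mean,
                                            config.depth_log_sd))))
        counts = rng.multinomial(depth, comp).astype(float)
        rows.append(counts / counts.sum())
        ids.append(("R" if y[i] else "N") + f"{i + 1:03d}.V01")
    X = pd.DataFrame(np.array(rows), index=ids,
                     columns=panel["lineage"].tolist())
    truth = GroundTruth(
        md_offset_cd=config.md_offset_cd,
        md_offset_uc=config.md_offset_uc,
        cal_slope=config.cal_slope,
        cal_intercept=config.cal_intercept,
        cal_extra_cd=config.cal_extra_cd,
        cal_extra_uc=config.cal_extra_uc,
        md_control_ref=_control_reference_md(panel, config.pseudocount),
        decay_fraction=config.decay_fraction,
        responder_genera={
            lin: off for lin, off in zip(panel["lineage"], nr_offset)
            if off != 0.0
        },
    )
    return X, y, truth
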
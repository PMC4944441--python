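"""Core in-memory containers for the dysbiosis pipeline.

Internally every table keeps samples on rows and taxa on columns; the
on-disk TSV convention is the transpose (taxa on rows), matching the
QIIME-1 ``summarize_taxa`` layout.  Lineage strings are semicolon-
delimited with rank prefixes (``k__;p__;c__;o__;f__;g__``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control_familial", "control_unrelated", "CD", "UC")
CONTROL_GROUPS = ("control_familial", "control_unrelated")
CASE_GROUPS = ("CD", "UC")
RESPONDER_LEVELS = ("responder", "non_responder", "not_applicable")

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")

_FREQ_TOL = 1e-9


class ValidationError(ValueError):
    """An input violated a structural invariant."""


@dataclass
class TaxonTable:
    """A samples-by-taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples on rows (index = sample IDs), taxa on columns
        (columns = lineage strings).  Non-negative.
    value_kind : {"counts", "frequencies", "frequencies_filtered"}
        Whether entries are read counts or per-sample relative
        abundances (each row summing to 1).  ``frequencies_filtered``
        marks a frequency table whose columns have been subset, so row
        sums may fall below 1 and the sum invariant is not enforced.
    """

    data: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "frequencies",
                                   "frequencies_filtered"):
            raise ValidationError(f"unknown value_kind: {self.value_kind!r}")
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon lineages: {dupes}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            raise ValidationError("negative abundance values")
        if self.value_kind == "frequencies":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _FREQ_TOL
            if bad.any():
                names = idx[bad].tolist()
                raise ValidationError(
                    f"frequency rows must sum to 1: offending samples {names}"
                )

    # -- accessors ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_lineages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total (read depth for count tables)."""
        return self.data.sum(axis=1)

    def copy(self) -> "TaxonTable":
        return TaxonTable(self.data.copy(), self.value_kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonTable):
            return NotImplemented
        return (
            self.value_kind == other.value_kind
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.data.to_numpy(), other.data.to_numpy(),
                            rtol=0, atol=1e-12)
        )


REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "responder",
    "time_days",
    "calprotectin",
    "activity_index",
    "pretreatment_flag",
)


@dataclass
class CohortMetadata:
    """Per-sample clinical and longitudinal covariates.

    One row per stool sample; ``subject_id`` defines the clusters used
    by the GEE stage.  ``calprotectin`` (ug/g) and ``activity_index``
    (PCDAI/PUCAI points) may be missing (NaN) — never encoded as zero.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df["calprotectin"] = pd.to_numeric(df["calprotectin"], errors="coerce")
        df["activity_index"] = pd.to_numeric(df["activity_index"], errors="coerce")
        df["time_days"] = pd.to_numeric(df["time_days"])
        if df["pretreatment_flag"].dtype != bool:
            df["pretreatment_flag"] = (
                df["pretreatment_flag"]
                .map({True: True, False: False, "True": True, "False": False,
                      "true": True, "false": False, 1: True, 0: False,
                      "1": True, "0": False})
            )
            if df["pretreatment_flag"].isna().any():
                raise ValidationError("unparseable pretreatment_flag values")
            df["pretreatment_flag"] = df["pretreatment_flag"].astype(bool)
        self.data = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dupes}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_resp = set(df["responder"]) - set(RESPONDER_LEVELS)
        if bad_resp:
            raise ValidationError(f"unknown responder labels: {sorted(bad_resp)}")
        if (df["subject_id"].astype(str).str.len() == 0).any():
            raise ValidationError("sample without subject ID")
        if df["subject_id"].isna().any():
            raise ValidationError("sample without subject ID")
        controls = df["group"].isin(CONTROL_GROUPS)
        if (df.loc[controls, "responder"] != "not_applicable").any():
            bad = df.loc[controls & (df["responder"] != "not_applicable"),
                         "sample_id"].tolist()
            raise ValidationError(
                f"control samples must have responder=not_applicable: {bad}"
            )
        if (df["time_days"] < 0).any():
            raise ValidationError("negative time_days")
        # pretreatment samples must be the earliest per subject
        pre = df[df["pretreatment_flag"]]
        for subj, grp in pre.groupby("subject_id"):
            earliest = df.loc[df["subject_id"] == subj, "time_days"].min()
            if (grp["time_days"] > earliest).any():
                raise ValidationError(
                    f"pretreatment_flag on a non-earliest sample of {subj}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def subjects(self) -> list[str]:
        return self.data["subject_id"].unique().tolist()

    def cluster_sizes(self) -> pd.Series:
        return self.data.groupby("subject_id").size()

    def is_case(self) -> pd.Series:
        return self.data["group"].isin(CASE_GROUPS)

    def subset(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return CohortMetadata(keep.copy())

    def aligned_to(self, table: TaxonTable) -> "CohortMetadata":
        """Rows reordered to match a table's samples; error on mismatch."""
        df = self.data.set_index("sample_id")
        missing = [s for s in table.sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        out = df.loc[table.sample_ids].reset_index()
        return CohortMetadata(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortMetadata):
            return NotImplemented
        a = self.data[list(REQUIRED_METADATA_COLUMNS)]
        b = other.data[list(REQUIRED_METADATA_COLUMNS)]
        if a.shape != b.shape:
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False,
                                          check_exact=False, atol=1e-12)
        except AssertionError:
            return False
        return True


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide constants and the master seed.

    Defaults follow the analysis protocol this package implements:
    samples under 3000 reads are dropped, rarefaction resamples to the
    minimum observed depth of 3155 reads 10,000 times, genera must
    exceed 0.15 % relative abundance in at least one sample, the forest
    uses 25,001 trees and 10,000 label permutations, and log-ratio
    metrics use a 1e-5 pseudocount.
    """

    seed: int = 0
    min_reads: int = 3000
    rarefaction_depth: int = 3155
    rarefaction_reps: int = 10000
    prevalence_threshold: float = 0.0015
    n_trees: int = 25001
    n_permutation_trees: int = 501
    n_permutations: int = 10000
    shannon_log_base: float = 2.0
    pseudocount: float = 1e-5
    unifrac_normalized: bool = False
    mtry: int | None = None  # None -> floor(sqrt(p))

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")
        for name in ("rarefaction_depth", "rarefaction_reps", "n_trees",
                     "n_permutation_trees"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_permutations < 0:
            raise ValidationError("n_permutations must be >= 0")
        if not 0 < self.prevalence_threshold < 1:
            raise ValidationError("prevalence_threshold must be in (0,1)")
        if not 0 < self.pseudocount < 1:
            raise ValidationError("pseudocount must be in (0,1)")
        if self.shannon_log_base not in (2.0, np.e):
            raise ValidationError("shannon_log_base must be 2 or e")

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for one named pipeline stage.

    Each stochastic stage derives its stream from ``(seed, stage
    name)``, so adding or reordering stages never perturbs the numbers
    another stage draws.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def stage_seed(seed: int, stage: str) -> int:
    """A 31-bit integer child seed for stages that need a plain seed."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
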
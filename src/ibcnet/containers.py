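"""Shared in-memory containers for the pipeline.

Expression data travel as pandas objects: a genes x samples float DataFrame
plus a per-sample annotation DataFrame. Thin dataclasses bundle them with
validation so every stage can rely on the same invariants (unique sample ids,
annotation covering every sample, finite values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = (
    "batch",
    "replicate_group",
    "phenotype",
    "ER",
    "PR",
    "HER2",
    "subtype",
)


@dataclass
class ExpressionCompendium:
    """Log2 expression matrix (genes x samples) with per-sample annotation."""

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = self.values.columns.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"annotation missing for samples: {list(missing)[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        self.annotation = self.annotation.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "ExpressionCompendium":
        return ExpressionCompendium(self.values[samples], self.annotation.loc[samples])


@dataclass
class PerturbationCatalog:
    """Ranked perturbation signatures (genes x perturbagens) with metadata.

    ``meta`` has one row per perturbagen with columns ``type``
    (overexpression / knockdown / drug) and ``target`` (declared drug target
    perturbagen id, or empty string).
    """

    signatures: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.signatures.columns.duplicated().any():
            raise ValueError("duplicate perturbagen ids")
        if not set(self.signatures.columns) <= set(self.meta.index):
            raise ValueError("metadata missing for some perturbagens")
        bad = set(self.meta["type"]) - {"overexpression", "knockdown", "drug"}
        if bad:
            raise ValueError(f"unknown perturbagen types: {bad}")


@dataclass
class PatientCohort:
    """Per-sample patient table: expression of marker genes plus labels.

    ``data`` columns include at least ESR1, MYC, the PMN member genes,
    one or more ``activity_*`` score columns, and the categorical labels
    phenotype (IBC/nIBC), er_stratum (low/moderate/high), stage, subtype.
    """

    data: pd.DataFrame
    pmn_members: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        required = {"ESR1", "MYC", "phenotype", "er_stratum"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.data["phenotype"].isna().any():
            raise ValueError("phenotype must be complete")
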
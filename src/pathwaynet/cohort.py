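"""Multimodal cohort containers shared across the pipeline.

A cohort carries three aligned blocks — per-gene SNP aggregates, gene
expression, and a mixed clinical table — plus CN/MCI/AD labels and,
optionally, a train/validation/test split assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_ORDER = ("CN", "MCI", "AD")
CLASS_CODES = {label: code for code, label in enumerate(CLASS_ORDER)}

__all__ = ["CLASS_ORDER", "CLASS_CODES", "CohortDataset", "ProcessedCohort"]


@dataclass
class CohortDataset:
    """Aligned genotype / expression / clinical blocks with labels.

    All three DataFrames are indexed by the same sample ids in the same
    order; ``labels`` takes values in ``CLASS_ORDER``; ``split`` (if set)
    takes values in {"train", "validation", "test"}.
    """

    genotype: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    labels: pd.Series
    clinical_types: dict[str, str] = field(default_factory=dict)  # name -> continuous|categorical
    split: pd.Series | None = None
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.genotype.index
        for name, block in (("expression", self.expression), ("clinical", self.clinical)):
            if not block.index.equals(idx):
                raise ValueError(f"{name} block sample order differs from genotype block")
        if not self.labels.index.equals(idx):
            raise ValueError("labels sample order differs from genotype block")
        bad = set(self.labels.unique()) - set(CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.genotype.index)

    @property
    def n_samples(self) -> int:
        return len(self.genotype)

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(CLASS_ORDER).fillna(0).astype(int)

    def subset(self, sample_ids) -> "CohortDataset":
        return CohortDataset(
            genotype=self.genotype.loc[sample_ids],
            expression=self.expression.loc[sample_ids],
            clinical=self.clinical.loc[sample_ids],
            labels=self.labels.loc[sample_ids],
            clinical_types=dict(self.clinical_types),
            split=None if self.split is None else self.split.loc[sample_ids],
            manifest=dict(self.manifest),
        )

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            genotype=self.genotype.copy(),
            expression=self.expression.copy(),
            clinical=self.clinical.copy(),
            labels=self.labels.copy(),
            clinical_types=dict(self.clinical_types),
            split=None if self.split is None else self.split.copy(),
            manifest=dict(self.manifest),
        )

    def save(self, directory: str | Path) -> None:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.genotype.to_csv(directory / "genotype.tsv", sep="\t")
        self.expression.to_csv(directory / "expression.tsv", sep="\t")
        self.clinical.to_csv(directory / "clinical.csv")
        lab = self.labels.rename("label").to_frame()
        if self.split is not None:
            lab["split"] = self.split
        lab.to_csv(directory / "labels.csv")
        (directory / "clinical_types.json").write_text(json.dumps(self.clinical_types, indent=2))
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "CohortDataset":
        import json

        directory = Path(directory)
        genotype = pd.read_csv(directory / "genotype.tsv", sep="\t", index_col=0)
        expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
        clinical = pd.read_csv(directory / "clinical.csv", index_col=0)
        lab = pd.read_csv(directory / "labels.csv", index_col=0)
        types_path = directory / "clinical_types.json"
        manifest_path = directory / "manifest.json"
        return cls(
            genotype=genotype,
            expression=expression,
            clinical=clinical,
            labels=lab["label"],
            clinical_types=json.loads(types_path.read_text()) if types_path.exists() else {},
            split=lab["split"] if "split" in lab.columns else None,
            manifest=json.loads(manifest_path.read_text()) if manifest_path.exists() else {},
        )


@dataclass
class ProcessedCohort:
    """Model-ready tensors produced by the preprocessing chain.

    Feature order in every ``X`` block is ``[snp genes | expression genes |
    expanded clinical columns]``; ``slices`` maps modality name to the
    corresponding column slice.
    """

    X_train: np.ndarray
    y_train: np.ndarray  # integer codes, CN=0 MCI=1 AD=2
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    feature_names: list[str]
    modality: np.ndarray  # per-feature tag: snp | expression | clinical
    slices: dict[str, slice]
    fitted_params: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def block(self, X: np.ndarray, modality: str) -> np.ndarray:
        return X[:, self.slices[modality]]
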
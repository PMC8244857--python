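"""Core data containers for tissue-specificity analysis.

The pipeline works on a small set of tabular objects, all backed by pandas:

* :class:`ExpressionMatrix` -- genes x samples FPKM values plus a sample
  design table (group label, cancer/normal class, cancer->tissue pairing).
* :class:`MeanProfiles` -- genes x groups mean expression on the offset
  (FPKM+1) scale; the per-cancer-type / per-tissue mean statistics.
* Specificity, relative-expression, prognostic and distance tables are plain
  :class:`pandas.DataFrame` objects with documented column conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_CANCER = "cancer"
CLASS_NORMAL = "normal"

#: Required columns of a design table.
DESIGN_COLUMNS = ("sample", "group", "class", "paired_group")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id,
        holding non-negative FPKM-scale expression.
    design
        DataFrame with columns ``sample``, ``group``, ``class``
        (``"cancer"`` or ``"normal"``) and ``paired_group`` (for cancer
        samples, the id of the matched normal tissue; empty for normals).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = v.to_numpy()
        if np.isnan(arr).any():
            raise ValidationError("NaN values in expression matrix")
        if (arr < 0).any():
            raise ValidationError("negative expression values")
        d = self.design
        missing = set(DESIGN_COLUMNS[:3]) - set(d.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        if "paired_group" not in d.columns:
            d = d.assign(paired_group="")
            self.design = d
        if d["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in design table")
        unknown = set(v.columns) - set(d["sample"])
        if unknown:
            raise ValidationError(f"samples without a design row: {sorted(unknown)[:5]}")
        bad_class = set(d["class"]) - {CLASS_CANCER, CLASS_NORMAL}
        if bad_class:
            raise ValidationError(f"unknown sample classes: {sorted(bad_class)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def groups(self, cls: str | None = None) -> list[str]:
        """Group labels present among this matrix's samples, in design order."""
        d = self.design[self.design["sample"].isin(self.values.columns)]
        if cls is not None:
            d = d[d["class"] == cls]
        return list(dict.fromkeys(d["group"]))

    def sample_groups(self) -> pd.Series:
        """Group label per sample, aligned to the matrix columns."""
        lut = self.design.set_index("sample")["group"]
        return lut.reindex(self.values.columns)

    def subset_class(self, cls: str) -> "ExpressionMatrix":
        """Restrict to samples of one class (``"cancer"`` or ``"normal"``)."""
        keep = self.design.loc[self.design["class"] == cls, "sample"]
        keep = [s for s in self.values.columns if s in set(keep)]
        return ExpressionMatrix(self.values[keep], self.design[self.design["sample"].isin(keep)].copy())


@dataclass
class MeanProfiles:
    """Genes x groups mean expression on the offset (FPKM+offset) scale.

    ``values`` is indexed by gene id with one column per group.  ``classes``
    maps each group to ``"cancer"`` or ``"normal"``.  The per-gene
    cross-group average (the c-bar / n-bar statistic) is
    :meth:`cross_group_mean`.
    """

    values: pd.DataFrame
    classes: pd.Series
    offset: float = 1.0

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.classes.index):
            raise ValidationError("group classes do not match mean-profile columns")
        self.classes = self.classes.reindex(self.values.columns)
        if (self.values.to_numpy() < self.offset - 1e-12).any():
            raise ValidationError(f"mean values below the offset ({self.offset})")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def groups(self, cls: str | None = None) -> list[str]:
        if cls is None:
            return list(self.values.columns)
        return [g for g in self.values.columns if self.classes[g] == cls]

    def of_class(self, cls: str) -> "MeanProfiles":
        cols = self.groups(cls)
        return MeanProfiles(self.values[cols], self.classes[cols], self.offset)

    def cross_group_mean(self, cls: str | None = None) -> pd.Series:
        """Per-gene average of the group means (optionally one class only)."""
        return self.values[self.groups(cls)].mean(axis=1)


@dataclass
class GroundTruth:
    """Generative ground truth of a synthetic cohort.

    ``specific_genes`` maps each tissue to its block of truly
    tissue-specific genes (blocks are disjoint).  ``cancer_axis_genes`` is
    the fixed gene subset shifted in every cancer.  ``survival_coefficients``
    maps each cancer to a gene -> true log-hazard coefficient dict
    (negative = protective / favorable).
    """

    specific_genes: dict[str, list[str]]
    cancer_axis_genes: list[str]
    survival_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tissue, genes in self.specific_genes.items():
            block = set(genes)
            if block & seen:
                raise ValidationError(f"tissue-specific blocks overlap at tissue {tissue}")
            seen |= block

    def tissue_of(self, gene: str) -> str | None:
        for tissue, genes in self.specific_genes.items():
            if gene in genes:
                return tissue
        return None
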
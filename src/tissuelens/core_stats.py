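"""Group-mean, specificity and relative-expression statistics.

Given an expression matrix normalised as FPKM, the pipeline works with three
gene-level summaries per group (cancer type or normal tissue):

* the group mean on the FPKM+1 scale (``c`` for cancers, ``n`` for tissues),
* the specificity value ``log2(group mean / cross-group per-gene average)``
  (``c*`` / ``n*``), which is large and positive for genes elevated in one
  group relative to the panel average, and
* the cancer/normal relative expression ``r = log2(c / n)`` computed over
  the cancer <-> paired-tissue mapping.

All logs are base 2.  The +1 offset is applied to per-sample FPKM before
averaging; both the offset and an exclude-self variant of the cross-group
average are configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MeanProfiles, ValidationError

logger = logging.getLogger(__name__)


def compute_group_means(expr: ExpressionMatrix, offset: float = 1.0) -> MeanProfiles:
    """Per-group mean expression on the offset scale.

    For group j and gene i the value is ``mean over samples of group j of
    (FPKM + offset)``, so a gene with zero expression everywhere maps to
    ``offset``.

    Raises
    ------
    ValidationError
        If any group has no samples (cannot happen for groups derived from
        the design) or the matrix contains NaN (checked at construction).
    """
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    sample_groups = expr.sample_groups()
    if sample_groups.isna().any():
        raise ValidationError("samples without a group label")
    shifted = expr.values + offset
    means = shifted.T.groupby(sample_groups, sort=False).mean().T
    # preserve first-appearance group order from the design
    order = expr.groups()
    means = means[order]
    cls_lut = (
        expr.design.drop_duplicates("group").set_index("group")["class"]
    )
    classes = cls_lut.reindex(means.columns)
    return MeanProfiles(means, classes, offset=offset)


def compute_specificity(
    means: MeanProfiles,
    class_filter: str,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Specificity values ``log2(mean(i,j) / cross-group average of gene i)``.

    The denominator averages over *all* groups of the requested class,
    including group j itself (``exclude_self=True`` switches to a
    leave-one-out average).  Returns a genes x groups DataFrame; for the
    normal class these are the n* statistics, for the cancer class the c*
    statistics.
    """
    sub = means.of_class(class_filter)
    cols = list(sub.values.columns)
    if len(cols) < 2:
        raise ValidationError(
            f"specificity needs >=2 groups of class {class_filter!r}, got {len(cols)}"
        )
    m = sub.values.to_numpy(dtype=float)
    if exclude_self:
        k = m.shape[1]
        denom = (m.sum(axis=1, keepdims=True) - m) / (k - 1)
    else:
        denom = m.mean(axis=1, keepdims=True)
    spec = np.log2(m / denom)
    return pd.DataFrame(spec, index=sub.values.index, columns=cols)


def compute_relative_expression(
    cancer_means: MeanProfiles,
    normal_means: MeanProfiles,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Relative expression ``r = log2(cancer mean / paired-tissue mean)``.

    One column per cancer; tissues shared by several cancers (e.g. one
    kidney profile serving three renal cancers) are reused.  Computed on the
    intersection of gene ids, preserving the cancer matrix's gene order.
    """
    cancers = cancer_means.groups()
    for cancer in pairing:
        if cancer not in cancers:
            raise KeyError(f"pairing references unknown cancer group {cancer!r}")
    tissues = set(normal_means.values.columns)
    for cancer, tissue in pairing.items():
        if tissue not in tissues:
            raise KeyError(f"cancer {cancer!r} paired with unknown tissue {tissue!r}")
    shared = [g for g in cancer_means.gene_ids if g in set(normal_means.gene_ids)]
    if not shared:
        raise ValidationError("no shared genes between cancer and normal matrices")
    dropped = len(cancer_means.gene_ids) - len(shared)
    if dropped:
        logger.info("dropping %d genes absent from the normal matrix", dropped)
    out = {}
    for cancer in cancers:
        if cancer not in pairing:
            raise KeyError(f"cancer group {cancer!r} missing from pairing")
        tissue = pairing[cancer]
        c = cancer_means.values.loc[shared, cancer].to_numpy(dtype=float)
        n = normal_means.values.loc[shared, tissue].to_numpy(dtype=float)
        out[cancer] = np.log2(c / n)
    return pd.DataFrame(out, index=pd.Index(shared, name=cancer_means.gene_ids.name))
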
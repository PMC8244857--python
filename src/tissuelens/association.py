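"""Correlation analyses linking cancers to their normal tissues.

Three rank-correlation summaries per cancer:

* the Spearman correlation between a cancer's mean expression and each
  normal tissue's mean expression, with the best-matching tissue flagged;
* ``rho_cancer_norm``: Spearman between normal tissue-specificity (n*) and
  cancer/normal relative expression (r); universally negative when
  tissue-specific genes are down-regulated in the paired cancer
  (dedifferentiation);
* ``rho_surv``: Spearman between n* and the signed log-p prognostic score
  (s); positive when tissue-specific genes are favorably prognostic.

Plus the pairwise fold-change correlation matrix: for each cancer pair
(a, b) the Pearson correlation between the gene-wise cancer fold-change
vector v_c = c_a / c_b and the normal fold-change vector v_n = n_a / n_b,
with an optional exclusion of genes whose normal fold-change is outside
(fc_low, fc_high).  Lower filtered correlations indicate that removing
normal-tissue DE genes yields cancer contrasts distinct from normal-tissue
biology.

Only correlation point estimates are reported; the gene-level dependence
structure makes nominal p-values meaningless at these n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MeanProfiles, ValidationError

logger = logging.getLogger(__name__)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average (mid-rank) ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: Spearman correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def cancer_normal_correlation(
    cancer_means: MeanProfiles,
    normal_means: MeanProfiles,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Per-cancer Spearman correlation with the paired tissue and best match.

    Columns: ``tissue``, ``correlation`` (with the paired tissue),
    ``most_correlated`` (argmax over all tissues), ``paired_is_best``.
    Ties in the argmax are broken by lexicographic tissue id with a warning.
    """
    shared = [g for g in cancer_means.gene_ids if g in set(normal_means.gene_ids)]
    if len(shared) < 5:
        raise ValidationError("need >=5 shared genes for rank correlation")
    tissues = list(normal_means.values.columns)
    rows = []
    for cancer in cancer_means.values.columns:
        c = cancer_means.values.loc[shared, cancer].to_numpy()
        corrs = {t: spearman(c, normal_means.values.loc[shared, t].to_numpy()) for t in tissues}
        best_val = max(corrs.values())
        best = sorted(t for t, v in corrs.items() if v == best_val)
        if len(best) > 1:
            logger.warning("best-match tie for %s: %s; using %s", cancer, best, best[0])
        paired = pairing[cancer]
        rows.append(
            {
                "cancer": cancer,
                "tissue": paired,
                "correlation": corrs[paired],
                "most_correlated": best[0],
                "paired_is_best": best[0] == paired,
            }
        )
    return pd.DataFrame(rows).set_index("cancer")


@dataclass
class CorrelationFit:
    """A rank correlation with a least-squares line for scatter annotation."""

    rho: float
    slope: float
    intercept: float


def _corr_with_fit(x: np.ndarray, y: np.ndarray) -> CorrelationFit:
    rho = spearman(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationFit(rho, float(slope), float(intercept))


def specificity_vs_relative(spec_col: pd.Series, rel_col: pd.Series) -> CorrelationFit:
    """rho_cancer_norm: Spearman(n*, r) on shared genes, with an LS line."""
    shared = spec_col.index.intersection(rel_col.index)
    return _corr_with_fit(spec_col.loc[shared].to_numpy(), rel_col.loc[shared].to_numpy())


def specificity_vs_survival(spec_col: pd.Series, s_col: pd.Series) -> CorrelationFit:
    """rho_surv: Spearman(n*, s) on shared genes, with an LS line."""
    shared = spec_col.index.intersection(s_col.index)
    return _corr_with_fit(spec_col.loc[shared].to_numpy(), s_col.loc[shared].to_numpy())


@dataclass
class FoldChangeCorrelation:
    """Pairwise cancer-vs-normal fold-change correlations.

    ``unfiltered`` and ``filtered`` are cancer x cancer DataFrames (diagonal
    NaN); ``retained`` counts genes surviving the normal-DE exclusion per
    pair; ``fc_low``/``fc_high`` record the thresholds.
    """

    unfiltered: pd.DataFrame
    filtered: pd.DataFrame
    retained: pd.DataFrame
    fc_low: float
    fc_high: float


def pairwise_fc_correlation(
    cancer_means: MeanProfiles,
    normal_means: MeanProfiles,
    pairing: dict[str, str],
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    log_ratios: bool = False,
) -> FoldChangeCorrelation:
    """Pearson correlation of cancer vs normal fold-change vectors per pair.

    For cancers a, b: v_c[i] = c[i,a]/c[i,b] and v_n[i] = n[i,a]/n[i,b] on
    the offset mean scale (all ratios finite).  The filtered variant first
    removes genes with v_n <= fc_low or >= fc_high from both vectors.  With
    ``log_ratios`` both vectors are log2-transformed before the Pearson
    correlation, which makes the statistic symmetric under swapping a and b.
    """
    cancers = list(cancer_means.values.columns)
    if len(cancers) < 2:
        raise ValidationError("need >=2 cancers")
    shared = [g for g in cancer_means.gene_ids if g in set(normal_means.gene_ids)]
    C = cancer_means.values.loc[shared]
    N = normal_means.values.loc[shared]
    k = len(cancers)
    unf = pd.DataFrame(np.nan, index=cancers, columns=cancers)
    fil = pd.DataFrame(np.nan, index=cancers, columns=cancers)
    ret = pd.DataFrame(0, index=cancers, columns=cancers, dtype=int)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a, b = cancers[i], cancers[j]
            vc = C[a].to_numpy() / C[b].to_numpy()
            vn = N[pairing[a]].to_numpy() / N[pairing[b]].to_numpy()
            if log_ratios:
                vc, vn = np.log2(vc), np.log2(vn)
                keep = (vn > np.log2(fc_low)) & (vn < np.log2(fc_high))
            else:
                keep = (vn > fc_low) & (vn < fc_high)
            unf.loc[a, b] = _pearson_or_nan(vc, vn)
            ret.loc[a, b] = int(keep.sum())
            if keep.sum() >= 3:
                fil.loc[a, b] = _pearson_or_nan(vc[keep], vn[keep])
            else:
                logger.warning("pair (%s, %s): <3 genes retained, cell missing", a, b)
    return FoldChangeCorrelation(unf, fil, ret, fc_low, fc_high)


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
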
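"""Pre-ranked competitive gene-set testing and Q-Q power comparison.

The test asks, for each gene set, whether its members have systematically
larger or smaller ranking statistics (e.g. cancer/normal relative
expression) than the non-members.  The statistic is the difference of in-set
and out-of-set means scaled by the pooled standard deviation and a
variance-inflation factor VIF = 1 + (m - 1) * rho accounting for inter-gene
correlation (m = set size, rho defaulting to 0.01); the scaled statistic is
referred to a t distribution on G - 2 degrees of freedom.  With rho = 0 this
reduces exactly to the ordinary pooled two-sample t-test.  A rank-based
variant replaces the statistics by mid-ranks before the same comparison.

Directional analyses set the p-value of any set enriched opposite the
target direction to 1.0, and Q-Q comparison of p-value lists (all genes vs
specificity-filtered genes) quantifies the power gained by filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


# --- GMT gene-set collections ---------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(m for m in members if m))
            if len(deduped) < len([m for m in members if m]):
                logger.warning("%s:%d: duplicate members in %s deduplicated", path, lineno, name)
            sets[name] = deduped
            descriptions[name] = desc
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    """Write a gene-set collection as GMT."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# --- competitive pre-ranked test ------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-set outcome of the competitive pre-ranked test."""

    name: str
    n_members: int
    direction: str
    p: float
    directional_p: float = 1.0


def camera_pr(
    gene_stats: pd.Series,
    sets: dict[str, list[str]],
    inter_gene_corr: float = 0.01,
    use_ranks: bool = False,
) -> pd.DataFrame:
    """Competitive pre-ranked gene-set test with inter-gene correlation.

    Parameters
    ----------
    gene_stats
        Per-gene ranking statistic indexed by gene id.
    sets
        Set name -> member gene ids; members absent from ``gene_stats`` are
        ignored and sets with fewer than 2 measured members (or fewer than
        2 non-members) are skipped with a warning.
    inter_gene_corr
        Assumed within-set inter-gene correlation rho; the variance of the
        in-set mean is inflated by ``1 + (m - 1) * rho``.
    use_ranks
        Replace statistics by mid-ranks before testing.

    Returns a DataFrame indexed by set name with columns ``n_members``,
    ``direction`` (up iff in-set mean exceeds out-set mean), ``p``
    (two-sided) and ``t`` (the scaled statistic).
    """
    if inter_gene_corr < 0:
        raise ValidationError("inter_gene_corr must be non-negative")
    values = gene_stats.to_numpy(dtype=float)
    if use_ranks:
        values = stats.rankdata(values)
    G = len(values)
    if G < 4:
        raise ValidationError("need at least 4 measured genes")
    mean_all = values.mean()
    var_all = values.var(ddof=1)
    index = pd.Index(gene_stats.index)
    rows = []
    for name, members in sets.items():
        mask = index.isin(members)
        m = int(mask.sum())
        m2 = G - m
        if m < 2 or m2 < 2:
            logger.warning("set %s: %d measured members, skipped", name, m)
            continue
        mean_in = values[mask].mean()
        delta = G / m2 * (mean_in - mean_all)  # = mean_in - mean_out
        var_pooled = ((G - 1) * var_all - delta**2 * m * m2 / G) / (G - 2)
        if var_pooled <= 0:
            raise ValidationError(f"set {name}: zero pooled variance, test degenerate")
        vif = 1.0 + (m - 1) * inter_gene_corr
        t = delta / math.sqrt(var_pooled * (vif / m + 1.0 / m2))
        p = 2.0 * stats.t.sf(abs(t), df=G - 2)
        rows.append(
            {
                "set": name,
                "n_members": m,
                "direction": UP if delta > 0 else DOWN,
                "p": min(max(p, np.finfo(float).tiny), 1.0),
                "t": t,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def directionalize(results: pd.DataFrame, target: str) -> pd.DataFrame:
    """Directional p-values: sets enriched opposite ``target`` get p = 1.0."""
    if target not in (UP, DOWN):
        raise ValidationError(f"target must be up/down, got {target!r}")
    out = results.copy()
    out["directional_p"] = np.where(out["direction"] == target, out["p"], 1.0)
    return out


# --- specificity / tissue-DE gene filters ---------------------------------


def filter_by_specificity(
    spec_col: pd.Series,
    fraction: float = 0.2,
    mode: str = "remove_most_specific",
) -> pd.Index:
    """Drop the ceil(fraction * G) genes at one specificity extreme.

    ``remove_most_specific`` drops the genes with the largest n* (used when
    testing for up-regulation in cancer); ``remove_least_specific`` drops
    the smallest (used for down-regulation, keeping tissue-specific genes).
    Boundary ties are broken by gene id order with a warning.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    if mode not in ("remove_most_specific", "remove_least_specific"):
        raise ValidationError(f"unknown mode {mode!r}")
    G = len(spec_col)
    n_drop = math.ceil(fraction * G)
    ordered = spec_col.sort_values(
        ascending=(mode == "remove_least_specific"), kind="stable"
    )
    boundary = ordered.iloc[n_drop - 1]
    if (spec_col == boundary).sum() > 1:
        logger.warning("specificity ties at the filter boundary; gene-id order used")
    dropped = set(ordered.index[:n_drop])
    return spec_col.index[~spec_col.index.isin(dropped)]


def filter_by_tissue_de(
    normal_means: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    keep: str = "neutral",
) -> pd.Index:
    """Filter genes by fold-change between two normal tissues.

    ``keep="neutral"`` retains genes with fold-change strictly inside
    (fc_low, fc_high) -- removing normal-tissue DE before a comparative
    cancer analysis; ``keep="extreme"`` retains the complement, which
    prioritizes normal-tissue DE genes instead.
    """
    for t in (tissue_a, tissue_b):
        if t not in normal_means.columns:
            raise KeyError(f"tissue {t!r} not in normal means")
    if keep not in ("neutral", "extreme"):
        raise ValidationError(f"keep must be neutral/extreme, got {keep!r}")
    fc = normal_means[tissue_a].to_numpy() / normal_means[tissue_b].to_numpy()
    neutral = (fc > fc_low) & (fc < fc_high)
    mask = neutral if keep == "neutral" else ~neutral
    kept = normal_means.index[mask]
    if len(kept) == 0:
        raise ValidationError("tissue-DE filter removed every gene")
    return kept


# --- Q-Q power comparison --------------------------------------------------


@dataclass
class QQReport:
    """Paired p-value quantiles of an all-genes vs a filtered analysis."""

    quantiles_all: np.ndarray
    quantiles_filtered: np.ndarray
    improvement_fraction: float
    n_all: int
    n_filtered: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p_all": self.quantiles_all, "p_filtered": self.quantiles_filtered}
        )


def qq_compare(p_all, p_filtered) -> QQReport:
    """Pair two sorted p-value lists quantile-by-quantile.

    When the lists differ in length the longer grid of order statistics is
    used and the shorter list is linearly interpolated at matching quantile
    levels.  The improvement fraction is the share of quantile points where
    the filtered p is strictly smaller.
    """
    a = np.sort(np.asarray(p_all, dtype=float))
    f = np.sort(np.asarray(p_filtered, dtype=float))
    for name, v in (("p_all", a), ("p_filtered", f)):
        if v.size == 0:
            raise ValidationError(f"{name} is empty")
        if (v <= 0).any() or (v > 1).any():
            raise ValidationError(f"{name} contains values outside (0, 1]")
    n = max(len(a), len(f))
    levels = (np.arange(n) + 0.5) / n
    qa = np.quantile(a, levels, method="linear")
    qf = np.quantile(f, levels, method="linear")
    frac = float(np.mean(qf < qa))
    return QQReport(qa, qf, frac, len(a), len(f))
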
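"""Per-gene survival association via expression-cutoff log-rank scans.

Each gene is dichotomized at a series of expression percentiles (20th-80th
by default); a two-group log-rank test is run at every cutoff and the cutoff
with the smallest p-value is retained, following the pathology-atlas
practice of scanning cutoffs without multiplicity correction.  The scan's
minimum-p is therefore anti-conservative -- deliberately so, since the
downstream prognostic score inherits the same construction; the bias is
documented and covered by a test rather than corrected.

The prognostic direction is *favorable* when the high-expression group has
the larger Kaplan-Meier restricted-mean survival, and the signed score is

    s = -log(p)  (favorable, positive)     s = +log(p)  (unfavorable, negative)

Natural log by default; the base only rescales s so every downstream rank
statistic is unaffected.

Specificity-based gene filtering for survival analysis removes genes
down-regulated in the paired tissue (n* < log2(0.8)) when hunting favorable
genes, or genes up-regulated there (n* > log2(1.2)) for unfavorable genes.

The log-rank machinery is vectorized over (gene, cutoff) pairs so a full
genome scan for one cancer is a single pass over the event-time grid.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

logger = logging.getLogger(__name__)

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"

#: default n* filter bounds: plain fold-change 0.8x / 1.2x on the log2 scale
SPEC_LOW = math.log2(0.8)
SPEC_HIGH = math.log2(1.2)


def _logrank_core(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square and p for R group assignments at once.

    ``groups`` is an (R, n) boolean matrix; each row defines membership of
    the comparison group.  Returns (stat, p), each of shape (R,).
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    G = groups[:, order].astype(float)

    # distinct time blocks; reduceat segment starts
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_at_risk = len(t) - starts  # subjects with time >= t_k
    d = np.add.reduceat(e, starts)  # events at t_k
    # at-risk in the comparison group: suffix sums evaluated at block starts
    suffix = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]
    d1 = np.add.reduceat(e[None, :] * G, starts, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_at_risk[None, :]
        expected = d[None, :] * frac
        var = d[None, :] * frac * (1.0 - frac) * (n_at_risk - d)[None, :] / np.maximum(
            n_at_risk - 1, 1
        )[None, :]
    o_minus_e = (d1 - expected).sum(axis=1)
    v = var.sum(axis=1)
    stat = np.zeros(len(v))
    np.divide(o_minus_e**2, v, out=stat, where=v > 0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(v > 0, p, 1.0)
    return stat, np.clip(p, np.finfo(float).tiny, 1.0)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df).

    ``group`` is a binary/boolean label per subject.  Returns
    ``(statistic, p)``; with zero events the test is degenerate and
    ``(0.0, 1.0)`` is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group).astype(bool)
    if times.shape != events.shape or times.shape != group.shape:
        raise ValidationError("times, events and group must have equal length")
    if group.all() or (~group).all():
        raise ValidationError("both groups must be non-empty")
    if events.sum() == 0:
        logger.warning("no events observed: log-rank degenerate, returning p=1")
        return 0.0, 1.0
    stat, p = _logrank_core(times, events, group[None, :])
    return float(stat[0]), float(p[0])


def _km_rmst(
    d_grp: np.ndarray, n_grp: np.ndarray, t_k: np.ndarray, tau: float
) -> np.ndarray:
    """Restricted-mean survival from grouped event counts, vectorized.

    ``d_grp``/``n_grp`` are (R, K) events and at-risk counts per distinct
    time; the KM curve steps at those times and the integral runs to tau.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = 1.0 - np.where(n_grp > 0, d_grp / np.maximum(n_grp, 1), 0.0)
    S = np.cumprod(factor, axis=1)
    # integral of the step function: 1 on [0, t_1), S_k on [t_k, t_{k+1})
    edges = np.r_[t_k, tau]
    widths = np.diff(edges)
    return edges[0] + (S * widths[None, :]).sum(axis=1)


def scan_cutoffs_matrix(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    lo_pct: float = 20,
    hi_pct: float = 80,
    step_pct: float = 1,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Cutoff-scan log-rank for every gene of a genes x samples matrix.

    ``surv`` must have columns ``sample``, ``time``, ``event``; only
    samples present in both tables are used.  Returns a prognostic table
    with columns ``cutoff``, ``cutoff_pct``, ``p``, ``direction``, ``s``
    indexed by gene.  Constant-expression genes are skipped with a log
    message.
    """
    surv = surv.set_index("sample") if "sample" in surv.columns else surv
    shared = [s for s in expr.columns if s in surv.index]
    if len(shared) < 10:
        raise ValidationError("need >=10 subjects with expression and survival")
    times = surv.loc[shared, "time"].to_numpy(dtype=float)
    events = surv.loc[shared, "event"].to_numpy(dtype=int)
    if (times <= 0).any():
        raise ValidationError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    X = expr[shared].to_numpy(dtype=float)

    keep = np.ptp(X, axis=1) > 0
    if not keep.all():
        logger.info("skipping %d constant-expression genes", int((~keep).sum()))
    Xv = X[keep]
    genes = expr.index[keep]
    n_genes = Xv.shape[0]
    if n_genes == 0:
        return pd.DataFrame(columns=["cutoff", "cutoff_pct", "p", "direction", "s"])

    pcts = np.arange(lo_pct, hi_pct + 1e-9, step_pct)
    cutoffs = np.percentile(Xv, pcts, axis=1).T  # genes x cutoffs
    # group = high expression (strictly above the cutoff)
    G = Xv[:, None, :] > cutoffs[:, :, None]  # genes x cutoffs x samples
    flat = G.reshape(n_genes * len(pcts), len(shared))
    valid = flat.any(axis=1) & (~flat).any(axis=1)

    stat = np.zeros(flat.shape[0])
    p = np.ones(flat.shape[0])
    if events.sum() > 0 and valid.any():
        stat_v, p_v = _logrank_core(times, events, flat[valid])
        stat[valid] = stat_v
        p[valid] = p_v
    p_mat = np.where(valid, p, np.inf).reshape(n_genes, len(pcts))
    best = p_mat.argmin(axis=1)  # first minimum -> lowest percentile wins ties
    best_p = p_mat[np.arange(n_genes), best]
    degenerate = ~np.isfinite(best_p)
    best_p = np.where(degenerate, 1.0, np.minimum(best_p, 1.0))

    # direction from restricted-mean survival at the best cutoff
    Gbest = G[np.arange(n_genes), best]  # genes x samples
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order].astype(float)
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    t_k = t_sorted[starts]
    tau = float(t_sorted[-1])
    Gb = Gbest[:, order].astype(float)
    suffix = np.cumsum(Gb[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]
    d1 = np.add.reduceat(e_sorted[None, :] * Gb, starts, axis=1)
    n_tot = len(shared) - starts
    d_tot = np.add.reduceat(e_sorted, starts)
    rmst_high = _km_rmst(d1, n1, t_k, tau)
    rmst_low = _km_rmst(d_tot[None, :] - d1, n_tot[None, :] - n1, t_k, tau)
    favorable = rmst_high > rmst_low
    ties = rmst_high == rmst_low
    if ties.any():
        logger.warning(
            "%d genes with tied restricted-mean survival: direction set unfavorable",
            int(ties.sum()),
        )

    direction = np.where(favorable, FAVORABLE, UNFAVORABLE)
    s = np.array(
        [signed_log_p(pv, d, base=log_base) for pv, d in zip(best_p, direction)]
    )
    return pd.DataFrame(
        {
            "cutoff": cutoffs[np.arange(n_genes), best],
            "cutoff_pct": pcts[best],
            "p": best_p,
            "direction": direction,
            "s": s,
        },
        index=pd.Index(genes, name="gene"),
    )


def scan_cutoffs(
    expr_vector: pd.Series,
    surv: pd.DataFrame,
    lo_pct: float = 20,
    hi_pct: float = 80,
    step_pct: float = 1,
    log_base: float = math.e,
) -> pd.Series:
    """Cutoff-scan log-rank for a single gene; see :func:`scan_cutoffs_matrix`."""
    if expr_vector.nunique() <= 1:
        raise ValidationError("constant expression: cutoff scan undefined")
    table = scan_cutoffs_matrix(
        expr_vector.to_frame().T, surv, lo_pct, hi_pct, step_pct, log_base
    )
    return table.iloc[0]


def signed_log_p(p: float, direction: str, base: float = math.e) -> float:
    """Signed log p-value: positive for favorable genes, negative otherwise."""
    if not 0 < p <= 1:
        raise ValidationError(f"p must be in (0, 1], got {p}")
    if direction not in (FAVORABLE, UNFAVORABLE):
        raise ValidationError(f"unknown direction {direction!r}")
    magnitude = -math.log(p, base)
    return magnitude if direction == FAVORABLE else -magnitude


def filter_for_survival(
    spec_col: pd.Series,
    mode: str,
    low: float = SPEC_LOW,
    high: float = SPEC_HIGH,
) -> pd.Index:
    """Specificity-based gene filter for survival analysis.

    ``mode="favorable"`` removes genes with n* below ``low`` (keeps genes
    not down-regulated in the paired tissue); ``mode="unfavorable"``
    removes genes with n* above ``high``.  Defaults are fold-change bounds
    0.8x and 1.2x expressed on the same (base-2) log scale as n*.
    """
    if mode == FAVORABLE:
        kept = spec_col.index[spec_col.to_numpy() >= low]
    elif mode == UNFAVORABLE:
        kept = spec_col.index[spec_col.to_numpy() <= high]
    else:
        raise ValidationError(f"mode must be favorable/unfavorable, got {mode!r}")
    if len(kept) == 0:
        raise ValidationError("specificity filter removed every gene")
    return kept


def directional_p_values(prog: pd.DataFrame, mode: str) -> pd.Series:
    """P-values of a prognostic table with the opposite direction set to 1.0."""
    p = prog["p"].copy()
    p[prog["direction"] != mode] = 1.0
    return p
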
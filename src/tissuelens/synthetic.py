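"""Synthetic coupled normal-tissue / cancer cohorts with survival.

The generator emulates the statistical structure the downstream analyses
assume in real pan-cancer data:

* per-gene baseline expression with a heavy right tail (log-normal FPKM,
  log2 mean ~ N(3, 2));
* for each tissue, a disjoint minority block of genes elevated specifically
  in that tissue (``frac_specific`` of genes, elevation ``specific_log2fc``
  in log2 units);
* each cancer coupled to its paired normal tissue, but (a) the
  tissue-specific elevation attenuated by the ``dedifferentiation`` factor
  (1 = fully retained; values below 1 model loss of tissue identity) and
  (b) a fixed random gene subset shifted by ``cancer_axis_log2fc`` in every
  cancer, producing the raw-scale cancer-vs-normal separation while leaving
  specificity values untouched (the shift is common to all cancers so it
  cancels in the cross-cancer average);
* per-sample activation noise on the tissue program and the cancer axis
  (``program_sd``), which makes both gene expression and hazard vary across
  subjects of one cancer;
* exponential survival with log-hazard ``surv_effect * (axis activation -
  tissue-program activation)``: retained tissue-program expression is
  protective, cancer-axis expression deleterious; independent uniform
  censoring calibrated to ``censor_rate``.

Everything is driven by a single seed; the full generative ground truth is
returned for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    CLASS_CANCER,
    CLASS_NORMAL,
    ExpressionMatrix,
    GroundTruth,
    ValidationError,
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's reference conditions: a desk-scale panel of
    6 tissues with one cancer each, 2000 genes, 3 donors per normal tissue
    (matching the Human Protein Atlas design) and 60 tumours per cancer.
    """

    n_genes: int = 2000
    n_tissues: int = 6
    cancers_per_tissue: int = 1
    samples_per_normal: int = 3
    samples_per_cancer: int = 60
    frac_specific: float = 0.05
    specific_log2fc: float = 3.0
    cancer_axis_log2fc: float = 2.0
    frac_cancer_axis: float = 0.10
    dedifferentiation: float = 0.5
    noise_sd: float = 0.5
    program_sd: float = 0.5
    surv_effect: float = 1.0
    censor_rate: float = 0.3
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "cancers_per_tissue": self.cancers_per_tissue,
            "samples_per_normal": self.samples_per_normal,
            "samples_per_cancer": self.samples_per_cancer,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        fracs = {
            "frac_specific": self.frac_specific,
            "frac_cancer_axis": self.frac_cancer_axis,
            "censor_rate": self.censor_rate,
            "dedifferentiation": self.dedifferentiation,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value!r}")
        for name in ("specific_log2fc", "cancer_axis_log2fc", "noise_sd", "program_sd", "surv_effect"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.frac_specific * self.n_tissues > 1.0 + 1e-12:
            raise ValidationError(
                "frac_specific * n_tissues must be <= 1 (disjoint tissue blocks)"
            )


def _censoring_horizon(lam: float, censor_rate: float) -> float:
    """Upper bound M of U(0, M) censoring so that P(C < T) = censor_rate
    when T ~ Exp(lam)."""

    def frac_censored(m: float) -> float:
        return (1.0 - np.exp(-lam * m)) / (lam * m)

    # frac_censored decreases from 1 (m -> 0) to 0 (m -> inf)
    lo, hi = 1e-9, 1.0
    while frac_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for censor_rate > 0
            break
    return brentq(lambda m: frac_censored(m) - censor_rate, lo, hi)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, dict[str, pd.DataFrame], GroundTruth]:
    """Generate coupled normal and cancer cohorts plus survival tables.

    Returns
    -------
    normal, cancer : ExpressionMatrix
        Strictly positive FPKM-scale expression for all normal and all
        cancer samples, with design tables.
    design : pandas.DataFrame
        Combined design (sample, group, class, paired_group).
    survival : dict of cancer id -> DataFrame(sample, time, event)
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tissues = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    cancers = [
        (f"cancer_{t:02d}" if config.cancers_per_tissue == 1 else f"cancer_{t:02d}_{k}", tissue)
        for t, tissue in enumerate(tissues)
        for k in range(config.cancers_per_tissue)
    ]
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]

    # --- ground-truth structure (drawn first so block sizes are
    # seed-independent of the noise stream only through rng order) ---
    block = int(round(config.frac_specific * config.n_genes))
    perm = rng.permutation(config.n_genes)
    specific = {
        tissue: sorted(perm[t * block : (t + 1) * block])
        for t, tissue in enumerate(tissues)
    }
    n_axis = int(round(config.frac_cancer_axis * config.n_genes))
    axis_idx = np.sort(rng.choice(config.n_genes, size=n_axis, replace=False))

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)

    # expected log2 profiles per group
    normal_log2 = {}
    for tissue in tissues:
        prof = baseline.copy()
        prof[specific[tissue]] += config.specific_log2fc
        normal_log2[tissue] = prof
    cancer_log2 = {}
    for cancer, tissue in cancers:
        prof = baseline.copy()
        prof[specific[tissue]] += config.dedifferentiation * config.specific_log2fc
        prof[axis_idx] += config.cancer_axis_log2fc
        cancer_log2[cancer] = prof

    # --- samples ---
    def noisy(profile: np.ndarray, n: int) -> np.ndarray:
        eps = np.zeros((len(profile), n))
        if config.noise_sd > 0:
            eps = rng.normal(0.0, config.noise_sd, size=(len(profile), n))
        return np.exp2(profile[:, None] + eps)

    norm_cols, norm_vals, design_rows = [], [], []
    for tissue in tissues:
        vals = noisy(normal_log2[tissue], config.samples_per_normal)
        for k in range(config.samples_per_normal):
            sid = f"{tissue}_s{k:03d}"
            norm_cols.append(sid)
            design_rows.append((sid, tissue, CLASS_NORMAL, ""))
        norm_vals.append(vals)
    normal_values = pd.DataFrame(
        np.hstack(norm_vals), index=pd.Index(genes, name="gene"), columns=norm_cols
    )

    canc_cols, canc_vals = [], []
    survival: dict[str, pd.DataFrame] = {}
    surv_coef: dict[str, dict[str, float]] = {}
    lam0 = 1.0
    horizon = (
        _censoring_horizon(lam0, config.censor_rate) if config.censor_rate > 0 else np.inf
    )
    for cancer, tissue in cancers:
        n = config.samples_per_cancer
        # per-sample activation of the tissue program and the cancer axis
        if config.program_sd > 0:
            u = rng.normal(0.0, config.program_sd, n)  # tissue-program activation
            w = rng.normal(0.0, config.program_sd, n)  # cancer-axis activation
        else:
            u = np.zeros(n)
            w = np.zeros(n)
        log2_expr = np.tile(cancer_log2[cancer][:, None], (1, n))
        log2_expr[specific[tissue], :] += u[None, :]
        log2_expr[axis_idx, :] += w[None, :]
        if config.noise_sd > 0:
            log2_expr = log2_expr + rng.normal(0.0, config.noise_sd, size=log2_expr.shape)
        vals = np.exp2(log2_expr)
        sids = [f"{cancer}_s{k:03d}" for k in range(n)]
        canc_cols.extend(sids)
        canc_vals.append(vals)
        for sid in sids:
            design_rows.append((sid, cancer, CLASS_CANCER, tissue))

        # exponential survival: protective tissue program, deleterious axis
        log_hazard = np.log(lam0) + config.surv_effect * (w - u)
        times = rng.exponential(1.0 / np.exp(log_hazard))
        if np.isfinite(horizon):
            cens = rng.uniform(0.0, horizon, n)
            event = (times <= cens).astype(int)
            times = np.minimum(times, cens)
        else:
            event = np.ones(n, dtype=int)
        times = np.maximum(times, 1e-9)
        survival[cancer] = pd.DataFrame({"sample": sids, "time": times, "event": event})

        coef: dict[str, float] = {}
        for g in specific[tissue]:
            coef[genes[g]] = -config.surv_effect
        for g in axis_idx:
            coef[genes[g]] = coef.get(genes[g], 0.0) + config.surv_effect
        surv_coef[cancer] = coef

    cancer_values = pd.DataFrame(
        np.hstack(canc_vals), index=pd.Index(genes, name="gene"), columns=canc_cols
    )
    design = pd.DataFrame(design_rows, columns=["sample", "group", "class", "paired_group"])

    truth = GroundTruth(
        specific_genes={t: [genes[g] for g in idx] for t, idx in specific.items()},
        cancer_axis_genes=[genes[g] for g in axis_idx],
        survival_coefficients=surv_coef,
    )
    normal_expr = ExpressionMatrix(normal_values, design[design["class"] == CLASS_NORMAL].copy())
    cancer_expr = ExpressionMatrix(cancer_values, design[design["class"] == CLASS_CANCER].copy())
    return normal_expr, cancer_expr, design, survival, truth


def pairing_from_design(design: pd.DataFrame) -> dict[str, str]:
    """Cancer group -> paired normal tissue map from a design table."""
    sub = design[(design["class"] == CLASS_CANCER) & (design["paired_group"] != "")]
    return dict(sub.drop_duplicates("group")[["group", "paired_group"]].itertuples(index=False))


def truth_recovery_report(
    truth: GroundTruth, specificity: pd.DataFrame, top_k: int
) -> dict[str, float]:
    """Fraction of true tissue-specific genes among the top-k by n* per tissue.

    Returns a tissue -> recovery fraction map; a tissue with an empty truth
    block maps to ``nan`` (recovery is undefined without true positives).
    """
    if top_k > specificity.shape[0]:
        raise ValidationError("top_k exceeds the number of genes")
    report: dict[str, float] = {}
    for tissue, true_genes in truth.specific_genes.items():
        if tissue not in specificity.columns:
            raise KeyError(f"tissue {tissue!r} absent from specificity matrix")
        if not true_genes:
            report[tissue] = float("nan")
            continue
        top = specificity[tissue].nlargest(top_k).index
        report[tissue] = len(set(top) & set(true_genes)) / len(true_genes)
    return report


def generate_gene_sets(
    truth: GroundTruth,
    gene_ids: list[str],
    n_sets: int = 50,
    min_size: int = 50,
    max_size: int = 200,
    signal_fraction: float = 0.4,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Hallmark-like synthetic gene-set collection over the cohort's genes.

    A third of the signal sets are enriched in cancer-axis genes (up in
    every cancer), the rest in tissue-program genes (down in cancer under
    dedifferentiation); remaining sets are uniform background.  Set sizes
    are uniform on [min_size, max_size].
    """
    rng = np.random.default_rng(seed)
    universe = np.asarray(gene_ids)
    axis = np.asarray(truth.cancer_axis_genes)
    program = np.asarray(sorted({g for gs in truth.specific_genes.values() for g in gs}))
    sets: dict[str, list[str]] = {}
    n_signal = int(round(signal_fraction * n_sets))
    for s in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        if s < n_signal and (len(axis) or len(program)):
            pool = axis if (s % 2 == 0 and len(axis)) else program
            n_sig = min(len(pool), max(2, size // 2))
            members = list(rng.choice(pool, size=n_sig, replace=False))
            rest = rng.choice(universe, size=size - n_sig, replace=False)
            members = sorted(set(members) | set(rest))
            name = f"SET_{'AXIS' if pool is axis else 'PROGRAM'}_{s:02d}"
        else:
            members = sorted(rng.choice(universe, size=size, replace=False))
            name = f"SET_RANDOM_{s:02d}"
        sets[name] = members
    return sets


# --- serialization ---------------------------------------------------------


def write_cohort(
    out_dir: str | Path,
    normal: ExpressionMatrix,
    cancer: ExpressionMatrix,
    design: pd.DataFrame,
    survival: dict[str, pd.DataFrame],
    truth: GroundTruth,
    config: SyntheticConfig | None = None,
) -> None:
    """Write a cohort as TSV/JSON files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    normal.values.to_csv(out / "expression_normal.tsv", sep="\t")
    cancer.values.to_csv(out / "expression_cancer.tsv", sep="\t")
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    for cancer_id, table in survival.items():
        table.to_csv(out / f"survival_{cancer_id}.tsv", sep="\t", index=False)
    truth_payload = {
        "specific_genes": truth.specific_genes,
        "cancer_axis_genes": truth.cancer_axis_genes,
        "survival_coefficients": truth.survival_coefficients,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))
    if config is not None:
        (out / "config.json").write_text(json.dumps(asdict(config), indent=1))


def read_expression(path: str | Path, design: pd.DataFrame) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV (first column = gene id)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    sub = design[design["sample"].isin(values.columns)].copy()
    return ExpressionMatrix(values, sub)
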
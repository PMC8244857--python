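"""Config-driven end-to-end pipeline.

Chains: simulate (or load) -> group-mean / specificity / relative-expression
statistics -> PCA embeddings and distance report -> correlation analyses ->
per-gene survival scan -> gene-set enrichment with specificity filtering ->
Q-Q power comparisons.  Every run writes a manifest recording the
parameters used (flagging overrides of the documented defaults), the files
produced and their checksums; all randomness flows from one root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CLASS_CANCER, CLASS_NORMAL, ValidationError
from . import association, core_stats, embedding, enrichment, survival, synthetic

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "stats", "embed", "associate", "survival", "enrich", "qq")

#: stage parameters with their reference defaults
DEFAULT_PARAMS = {
    "offset": 1.0,
    "pca_dims": 2,
    "pca_log": True,
    "fc_low": 0.5,
    "fc_high": 2.0,
    "filter_fraction": 0.2,
    "spec_low": survival.SPEC_LOW,
    "spec_high": survival.SPEC_HIGH,
    "scan_lo_pct": 20,
    "scan_hi_pct": 80,
    "scan_step_pct": 1,
    "inter_gene_corr": 0.01,
    "n_gene_sets": 50,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    seed = int(config.get("seed", 0))

    has_synthetic = "synthetic" in config
    has_inputs = "inputs" in config
    if not has_synthetic and not has_inputs:
        raise ValidationError("config needs either a 'synthetic' block or 'inputs' paths")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {
            name: {"value": value, "default": DEFAULT_PARAMS.get(name), "overridden": value != DEFAULT_PARAMS.get(name)}
            for name, value in params.items()
        },
        "outputs": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    # --- inputs -----------------------------------------------------------
    if has_synthetic:
        syn_kwargs = dict(config["synthetic"] or {})
        syn_kwargs.setdefault("seed", seed)
        cfg = synthetic.SyntheticConfig(**syn_kwargs)
        normal, cancer, design, surv_tables, truth = synthetic.generate_cohort(cfg)
        if "simulate" in stages:
            sim_dir = out / "simulate"
            synthetic.write_cohort(sim_dir, normal, cancer, design, surv_tables, truth, cfg)
            for f in sorted(sim_dir.iterdir()):
                record("simulate", f.name, f)
    else:
        inputs = config["inputs"]
        design = pd.read_csv(inputs["design"], sep="\t")
        normal = synthetic.read_expression(inputs["expr_normal"], design)
        cancer = synthetic.read_expression(inputs["expr_cancer"], design)
        surv_tables = {}
        for cancer_id, path in (inputs.get("survival") or {}).items():
            surv_tables[cancer_id] = pd.read_csv(path, sep="\t")
        truth = None
    pairing = synthetic.pairing_from_design(design)

    # --- statistics -------------------------------------------------------
    results: dict = {"design": design, "pairing": pairing, "truth": truth}
    if not ({"stats", "embed", "associate", "survival", "enrich", "qq"} & set(stages)):
        _write_manifest(out, manifest)
        return manifest

    cancer_means = core_stats.compute_group_means(cancer, offset=params["offset"])
    normal_means = core_stats.compute_group_means(normal, offset=params["offset"])
    c_star = core_stats.compute_specificity(cancer_means, CLASS_CANCER)
    n_star = core_stats.compute_specificity(normal_means, CLASS_NORMAL)
    rel = core_stats.compute_relative_expression(cancer_means, normal_means, pairing)
    results.update(
        cancer_means=cancer_means, normal_means=normal_means,
        c_star=c_star, n_star=n_star, relative_expression=rel,
    )
    if "stats" in stages:
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        for name, frame in (
            ("means_cancer", cancer_means.values),
            ("means_normal", normal_means.values),
            ("specificity_cancer", c_star),
            ("specificity_normal", n_star),
            ("relative_expression", rel),
        ):
            path = stats_dir / f"{name}.tsv"
            frame.to_csv(path, sep="\t")
            record("stats", name, path)

    # --- embedding --------------------------------------------------------
    if "embed" in stages:
        combined = pd.concat([cancer_means.values, normal_means.values], axis=1)
        classes = pd.concat([cancer_means.classes, normal_means.classes])
        raw_emb = embedding.fit_pca(combined, classes, log_transform=params["pca_log"])
        spec_combined = pd.concat([c_star, n_star], axis=1)
        spec_emb = embedding.fit_pca(spec_combined, classes, log_transform=False)
        report = embedding.distance_report(raw_emb, spec_emb, pairing, dims=params["pca_dims"])
        emb_dir = out / "embed"
        emb_dir.mkdir(exist_ok=True)
        for name, frame in (
            ("embedding_raw", raw_emb.coordinates),
            ("embedding_specificity", spec_emb.coordinates),
            ("distance_report", report),
        ):
            path = emb_dir / f"{name}.tsv"
            frame.to_csv(path, sep="\t")
            record("embed", name, path)
        results["distance_report"] = report

    # --- association ------------------------------------------------------
    if "associate" in stages:
        assoc_dir = out / "associate"
        assoc_dir.mkdir(exist_ok=True)
        corr = association.cancer_normal_correlation(cancer_means, normal_means, pairing)
        path = assoc_dir / "cancer_normal_correlation.tsv"
        corr.to_csv(path, sep="\t")
        record("associate", "cancer_normal_correlation", path)
        rho_rows = []
        for cancer_id, tissue in pairing.items():
            fit = association.specificity_vs_relative(n_star[tissue], rel[cancer_id])
            rho_rows.append({"cancer": cancer_id, "rho_cancer_norm": fit.rho})
        rho = pd.DataFrame(rho_rows).set_index("cancer")
        fc = association.pairwise_fc_correlation(
            cancer_means, normal_means, pairing,
            fc_low=params["fc_low"], fc_high=params["fc_high"],
        )
        for name, frame in (
            ("rho_cancer_norm", rho),
            ("fc_correlation_unfiltered", fc.unfiltered),
            ("fc_correlation_filtered", fc.filtered),
        ):
            path = assoc_dir / f"{name}.tsv"
            frame.to_csv(path, sep="\t")
            record("associate", name, path)
        results["rho_cancer_norm"] = rho
        results["fc_correlation"] = fc

    # --- survival ---------------------------------------------------------
    if "survival" in stages and surv_tables:
        surv_dir = out / "survival"
        surv_dir.mkdir(exist_ok=True)
        prognostic: dict[str, pd.DataFrame] = {}
        rho_surv_rows = []
        for cancer_id, table in surv_tables.items():
            expr_cols = [s for s in cancer.values.columns if s in set(table["sample"])]
            prog = survival.scan_cutoffs_matrix(
                cancer.values[expr_cols], table,
                lo_pct=params["scan_lo_pct"], hi_pct=params["scan_hi_pct"],
                step_pct=params["scan_step_pct"],
            )
            prognostic[cancer_id] = prog
            path = surv_dir / f"prognostic_{cancer_id}.tsv"
            prog.to_csv(path, sep="\t")
            record("survival", f"prognostic_{cancer_id}", path)
            tissue = pairing[cancer_id]
            fit = association.specificity_vs_survival(n_star[tissue], prog["s"])
            rho_surv_rows.append({"cancer": cancer_id, "rho_surv": fit.rho})
        rho_surv = pd.DataFrame(rho_surv_rows).set_index("cancer")
        path = surv_dir / "rho_surv.tsv"
        rho_surv.to_csv(path, sep="\t")
        record("survival", "rho_surv", path)
        results["prognostic"] = prognostic
        results["rho_surv"] = rho_surv

    # --- enrichment + qq ---------------------------------------------------
    if ("enrich" in stages or "qq" in stages) and truth is not None:
        gene_sets = synthetic.generate_gene_sets(
            truth, list(rel.index), n_sets=params["n_gene_sets"], seed=seed + 1,
        )
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        enrichment.write_gmt(gene_sets, enr_dir / "gene_sets.gmt")
        record("enrich", "gene_sets", enr_dir / "gene_sets.gmt")
        p_all: dict[str, list[float]] = {enrichment.UP: [], enrichment.DOWN: []}
        p_filt: dict[str, list[float]] = {enrichment.UP: [], enrichment.DOWN: []}
        for cancer_id, tissue in pairing.items():
            stats_col = rel[cancer_id]
            res_all = enrichment.camera_pr(stats_col, gene_sets, params["inter_gene_corr"])
            res_all.to_csv(enr_dir / f"enrichment_{cancer_id}.tsv", sep="\t")
            record("enrich", f"enrichment_{cancer_id}", enr_dir / f"enrichment_{cancer_id}.tsv")
            for target, mode in (
                (enrichment.UP, "remove_most_specific"),
                (enrichment.DOWN, "remove_least_specific"),
            ):
                kept = enrichment.filter_by_specificity(
                    n_star[tissue], fraction=params["filter_fraction"], mode=mode
                )
                res_f = enrichment.camera_pr(
                    stats_col.loc[kept], gene_sets, params["inter_gene_corr"]
                )
                p_all[target].extend(enrichment.directionalize(res_all, target)["directional_p"])
                p_filt[target].extend(enrichment.directionalize(res_f, target)["directional_p"])
        results["enrichment_p"] = {"all": p_all, "filtered": p_filt}
        if "qq" in stages:
            qq_dir = out / "qq"
            qq_dir.mkdir(exist_ok=True)
            for target in (enrichment.UP, enrichment.DOWN):
                report = enrichment.qq_compare(p_all[target], p_filt[target])
                path = qq_dir / f"qq_genesets_{target}.tsv"
                report.to_frame().to_csv(path, sep="\t", index=False)
                record("qq", f"qq_genesets_{target}", path)
                results[f"qq_genesets_{target}"] = report

    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
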
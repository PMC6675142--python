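"""End-to-end orchestration: preprocess -> FPCA -> clustering -> shapes ->
enrichment -> molecular evolution, with TSV outputs and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, enrichment, fpca, molevo, preprocess, shape_metrics

log = logging.getLogger(__name__)

DEFAULTS = {
    "threshold_cpm": 1.0,
    "min_timepoints": 1,
    "n_components": 2,
    "k_range": [2, 20],
    "n_restarts": 10,
    "seed": 0,
    "near_zero_ka": molevo.NEAR_ZERO_KA,
    "alpha": 0.05,
    "yates": False,
}


def load_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("ka", "ks"):
        if col in ann:
            ann[col] = pd.to_numeric(ann[col], errors="coerce")
    for col in ("operon", "has_ortholog"):
        if col in ann and ann[col].dtype == object:
            ann[col] = ann[col].map({"True": True, "False": False, True: True, False: False})
    return ann


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Run every stage on the configured inputs; returns the run manifest.

    ``config`` holds input paths (counts, sample_sheet, annotation, optional
    breakpoints+positions) and stage parameters (see DEFAULTS). Stage outputs
    are written as TSVs under ``outdir``; the manifest echoes every parameter
    and records row counts so reruns can be audited. Any stage failure aborts
    with the stage name and cause.
    """
    cfg = {**DEFAULTS, **config}
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "parameters": {k: v for k, v in cfg.items()},
                "stages": {}, "timestamp": datetime.now(timezone.utc).isoformat()}

    for key in ("counts", "sample_sheet", "annotation"):
        if key not in cfg:
            raise ValueError(f"config lacks required input path {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} path does not exist: {cfg[key]}")

    stage = "preprocess"
    try:
        ct = preprocess.read_counts(cfg["counts"], cfg["sample_sheet"],
                                    exclude_genes=cfg.get("exclude_genes"))
        ct, em = preprocess.filter_min_cpm(ct, cfg["threshold_cpm"], cfg["min_timepoints"])
        em.values.to_csv(outdir / "expression.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_genes": int(len(em.values)), "n_timepoints": int(em.values.shape[1]),
            "replicate_r": em.replicate_r}

        stage = "fpca"
        res = fpca.fit_fpca(em, n_components=cfg["n_components"])
        scores = fpca.scores_frame(res)
        scores.to_csv(outdir / "fpca_scores.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_components": res.n_components,
            "varfrac": [float(v) for v in res.varfrac],
            "cumulative_variance": fpca.variance_explained(res, res.n_components)}

        stage = "clustering"
        trace = clustering.select_k_by_bic(scores, range(cfg["k_range"][0], cfg["k_range"][1] + 1),
                                           n_restarts=cfg["n_restarts"], seed=cfg["seed"])
        trace.frame().to_csv(outdir / "bic_trace.tsv", sep="\t", index=False)
        ma = clustering.fit_gmm(scores, trace.chosen_k, n_restarts=cfg["n_restarts"],
                                seed=cfg["seed"])
        basis = shape_metrics.build_basis(em.values.shape[1])
        pre_alpha = {m: float(em.values.to_numpy()[ma.labels == m].mean())
                     for m in range(1, ma.k + 1)}
        ma = clustering.assign_modules(ma, module_alpha=pre_alpha)
        ma.frame().to_csv(outdir / "modules.tsv", sep="\t")
        manifest["stages"][stage] = {"chosen_k": trace.chosen_k,
                                     "module_sizes": {int(m): int((ma.labels == m).sum())
                                                      for m in range(1, ma.k + 1)}}

        stage = "shape_metrics"
        gene_fits = shape_metrics.fit_genes(em.values, basis)
        gene_fits.insert(0, "module", ma.labels)
        gene_fits.to_csv(outdir / "gene_shapes.tsv", sep="\t")
        trends = shape_metrics.module_trend_frame(em.values, ma.labels, basis)
        trends.to_csv(outdir / "module_trends.tsv", sep="\t")
        acc, conf, ridge = shape_metrics.discriminant_validation(gene_fits, ma.labels)
        dend = shape_metrics.cluster_module_coefficients(trends)
        (outdir / "module_dendrogram.nwk").write_text(dend.newick + "\n")
        manifest["stages"][stage] = {"discriminant_accuracy": acc, "ridge_used": ridge}

        stage = "enrichment"
        ann = load_annotation(cfg["annotation"])
        if cfg.get("breakpoints") and "position" in ann:
            bp = enrichment.read_breakpoints(cfg["breakpoints"])
            ann["domain"] = enrichment.assign_domains(
                ann[["chromosome", "position"]], bp)
        labels = pd.Series(ma.labels, index=em.values.index)
        chrom = enrichment.module_by_chromosome(labels, ann, alpha=cfg["alpha"],
                                                yates=cfg["yates"])
        chrom.to_csv(outdir / "enrichment_chromosome.tsv", sep="\t", index=False)
        dom = enrichment.module_by_domain(labels, ann, alpha=cfg["alpha"], yates=cfg["yates"])
        dom.to_csv(outdir / "enrichment_domain.tsv", sep="\t", index=False)
        arms = enrichment.module_arm_fractions(labels, ann)
        arms.to_csv(outdir / "module_arm_fractions.tsv", sep="\t")
        genesets = {}
        for which in ("operon", "gamete_class", "embryo_category"):
            if which in ann or which == "operon":
                gs = enrichment.module_by_geneset(labels, ann, which, alpha=cfg["alpha"],
                                                  yates=cfg["yates"])
                gs.to_csv(outdir / f"enrichment_{which}.tsv", sep="\t", index=False)
                genesets[which] = int(len(gs))
        manifest["stages"][stage] = {"n_chromosome_tests": int(len(chrom)),
                                     "n_domain_tests": int(len(dom)),
                                     "geneset_tests": genesets}

        stage = "molevo"
        summary = molevo.module_ka_summary(labels, ann, cfg["near_zero_ka"])
        summary.to_csv(outdir / "module_ka_summary.tsv", sep="\t")
        peaks = molevo.peak_timepoint(em.values)
        per_tp, per_stage = molevo.stage_ka_average(peaks, ann)
        per_tp.to_csv(outdir / "peak_timepoint_ka.tsv", sep="\t")
        per_stage.to_csv(outdir / "stage_ka.tsv", sep="\t")
        prof = molevo.tdi(em.values, ann)
        prof.values.to_csv(outdir / "tdi.tsv", sep="\t")
        reg = molevo.ka_shape_regression(gene_fits, ann)
        report = {"r_squared": reg.r_squared, "f_statistic": reg.f_statistic,
                  "df": [reg.df_model, reg.df_resid], "p_value": reg.p_value, "n": reg.n,
                  "coefficients": reg.coefficients.to_dict()}
        (outdir / "ka_shape_regression.json").write_text(json.dumps(report, indent=2))
        manifest["stages"][stage] = {"n_ka_genes": int(summary["n_ka"].sum()),
                                     "tdi_min_timepoint": int(prof.values.idxmin()),
                                     "regression_r2": reg.r_squared}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
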
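"""End-to-end pipelines: expression dosage analysis and qPCR Z-linkage.

Both pipelines read plain-text inputs, run the library stages in order and
write a reproducible report bundle (TSV/JSON plus a run manifest recording
the seed, all parameter values and the gene-count funnel at each filtering
step). Thresholds are configuration fields with the package defaults, never
constants buried in stage code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    ExpressionMatrix,
    QpcrPlate,
    read_annotation,
    read_orthology,
    write_mf_table,
)
from .dosage import (
    bias_expression_anova,
    chromosome_mf_regression,
    classify_sex_bias_series,
    mean_ratio_ci,
    za_ratio,
)
from .errors import ConfigurationError, InputError
from .gc import remove_gc_effect, sex_specific_gc_fits
from .quantify import (
    annotation_chromosomes,
    assign_chromosomes,
    compute_rpkm,
    filter_core_gene_set,
)
from .qpcr import ZlinkageQpcrModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the dosage pipeline (YAML-loadable).

    Paths may be None when a stage is skipped (no orthology file means
    chromosome labels are taken from the annotation directly).
    """

    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    orthology: str | None = None
    plate: str | None = None
    control_gene_id: str | None = None
    min_samples_per_sex: int = 2
    log2_mf_bound: float = 4.0
    expression_threshold: str = "per_individual"
    gc_correction: bool = True
    alpha: float = 0.05
    ratio_boundary: float = 1.5
    n_boot: int = 10_000
    seed: int = 0
    outdir: str = "zdosage_out"
    group_column: str = "group"
    stratify_by_group: bool = False
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def require(self, *fields_needed: str) -> None:
        for name in fields_needed:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"config field {name!r} is required for this pipeline")
            if name in ("counts", "samples", "annotation", "orthology", "plate") and not Path(value).exists():
                raise ConfigurationError(f"input file for {name!r} not found: {value}")


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_dosage_pipeline(config: PipelineConfig) -> dict:
    """quantify -> gc_correct -> dosage_stats, writing the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    config.require("counts", "samples", "annotation")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = ExpressionMatrix.read_tsv(config.counts, config.samples, unit="counts")
    annotation = read_annotation(config.annotation)
    funnel = {"genes_in": counts.n_genes}

    rpkm = compute_rpkm(counts, annotation)
    if config.orthology is not None:
        config.require("orthology")
        orthology = read_orthology(config.orthology)
        rpkm, chromosomes, n_dropped = assign_chromosomes(rpkm, orthology)
        funnel["genes_without_one2one_orthologue"] = n_dropped
    else:
        chromosomes = annotation_chromosomes(annotation)
    funnel["genes_after_orthology"] = rpkm.n_genes

    core, mf = filter_core_gene_set(
        rpkm,
        chromosomes,
        min_samples_per_sex=config.min_samples_per_sex,
        log2_mf_bound=config.log2_mf_bound,
        threshold=config.expression_threshold,
    )
    funnel["genes_after_filter"] = len(mf)

    gc_report = None
    if config.gc_correction:
        mf, gc_model, n_no_gc = remove_gc_effect(mf, annotation)
        sex_fits = sex_specific_gc_fits(core, annotation)
        gc_report = {
            "mf_fit": asdict(gc_model),
            "male_expression_fit": asdict(sex_fits["M"]),
            "female_expression_fit": asdict(sex_fits["F"]),
            "genes_without_gc": n_no_gc,
        }
        funnel["genes_after_gc"] = len(mf)

    mf = mf.merge(
        annotation["position_bp"].rename("position_bp"),
        left_on="gene_id",
        right_index=True,
        how="left",
    )
    write_mf_table(mf, outdir / "mf_table.tsv")

    results = chromosome_mf_regression(mf, alpha=config.alpha)
    chrom_out = results.chrom_table.copy()
    chrom_out.to_csv(outdir / "chrom_summary.tsv", sep="\t", index=False, float_format="%.6g")

    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)
    za = {
        sex: za_ratio(core, chromosomes, sex, n_boot=config.n_boot,
                      seed=np.random.default_rng(rng_seeds[i]))
        for i, sex in enumerate(("M", "F"))
    }
    autosomal = mf.loc[mf["chromosome"] != "Z", "mf_ratio"].to_numpy()
    am_af = mean_ratio_ci(
        autosomal, mode="geometric", n_boot=config.n_boot,
        seed=np.random.default_rng(rng_seeds[2]),
    )
    z_rows = mf.loc[mf["chromosome"] == "Z", "mf_ratio"].to_numpy()
    z_mf = (
        mean_ratio_ci(z_rows, mode="geometric", n_boot=config.n_boot,
                      seed=np.random.default_rng(rng_seeds[3]))
        if len(z_rows) >= 2
        else None
    )

    anova_report = {}
    classes = classify_sex_bias_series(mf["mf_ratio"])
    for sex, col in (("male", "mean_m"), ("female", "mean_f")):
        try:
            res = bias_expression_anova(np.log2(mf[col].to_numpy()), classes)
            anova_report[sex] = {
                "f_statistic": res.f_statistic,
                "df": [res.df_num, res.df_den],
                "p_value": res.p_value,
                "r_squared": res.r_squared,
                "class_sizes": res.class_sizes,
                "class_means_log2": res.class_means,
                "posthoc_bonferroni": {f"{a}|{b}": p for (a, b), p in res.posthoc.items()},
            }
        except InputError as exc:
            anova_report[sex] = {"skipped": str(exc)}
    _write_json(anova_report, outdir / "bias_anova.json")

    if config.make_plots:
        from . import plots

        plots.density_plot(mf, outdir / "density_log2mf.png")
        plots.chromosome_boxplot(mf, outdir / "chromosome_mf_boxplot.png")
        plots.bias_class_boxplot(mf, outdir / "bias_class_boxplot.png")

    manifest = {
        "tool": "zdosage",
        "version": __version__,
        "pipeline": "dosage",
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "funnel": funnel,
        "global_f": {
            "f_statistic": results.f_statistic,
            "df": [results.df_num, results.df_den],
            "p_value": results.f_pvalue,
        },
        "z_mf_ratio_ci": z_mf,
        "za_ratio": {s: list(v) for s, v in za.items()},
        "am_af_ratio_ci": list(am_af),
        "gc": gc_report,
    }

    if config.stratify_by_group and config.group_column in core.samples.columns:
        manifest["by_group"] = {}
        for grp, sheet in core.samples.groupby(config.group_column):
            sub = ExpressionMatrix(core.values[list(sheet.index)], sheet, core.unit)
            try:
                _, mf_g = filter_core_gene_set(
                    sub, chromosomes,
                    min_samples_per_sex=1,  # half the individuals per stratum
                    log2_mf_bound=config.log2_mf_bound,
                    threshold=config.expression_threshold,
                )
                res_g = chromosome_mf_regression(mf_g, alpha=config.alpha)
                res_g.chrom_table.to_csv(
                    outdir / f"chrom_summary_{grp}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                manifest["by_group"][str(grp)] = {"n_genes": len(mf_g)}
            except InputError as exc:
                manifest["by_group"][str(grp)] = {"skipped": str(exc)}

    _write_json(manifest, outdir / "manifest.json")
    return manifest


def run_qpcr_pipeline(config: PipelineConfig) -> dict:
    """ΔCt Z-linkage pipeline on a plate CSV, writing the report bundle."""
    config.require("plate", "control_gene_id")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    plate = QpcrPlate.read_csv(config.plate)
    if config.control_gene_id not in plate.gene_ids:
        raise ConfigurationError(
            f"control gene {config.control_gene_id!r} not found on plate {config.plate}"
        )
    results = ZlinkageQpcrModel(plate, config.control_gene_id).fit(
        alpha=config.alpha, ratio_boundary=config.ratio_boundary
    )
    results.locus_results.to_csv(
        outdir / "locus_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    results.calls.to_csv(outdir / "zlink_calls.tsv", sep="\t", index=False)

    counts = results.calls["call"].value_counts().to_dict()
    manifest = {
        "tool": "zdosage",
        "version": __version__,
        "pipeline": "qpcr",
        "seed": config.seed,
        "parameters": asdict(config),
        "n_genes": int(len(results.calls)),
        "calls": {k: int(v) for k, v in counts.items()},
        "control_gene_id": config.control_gene_id,
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
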
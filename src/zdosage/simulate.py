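"""Ground-truthed synthetic data for the dosage-compensation pipeline.

Three generators, all deterministic given a seed:

* :func:`simulate_expression` — an annotated read-count matrix for two sexes
  over autosomes plus one Z chromosome, with a tunable degree of dosage
  compensation. Males carry two Z copies; female Z output is scaled by
  ``2**d`` relative to a single copy, so the true male:female ratio of a
  Z-linked gene is ``2**(1 - d)`` (``d = 1`` full compensation, ``d = 0``
  none). Compensation is modelled as female up-regulation, which is the
  mechanism favoured for birds, though for the m:f ratio itself the
  male/female attribution is immaterial.
* :func:`simulate_qpcr` — a qPCR plate with replicate Ct values driven by
  genomic template copy number (ZZ males carry 2 Z copies, ZW females 1;
  autosomes carry 2 in both sexes) plus an autosomal normalizer gene.
* :func:`simulate_orthology` — a 1:1 orthology map in which a small fraction
  of genes has moved to a different chromosome since the split from the
  reference species (synteny disruption).

Counts are drawn negative-binomially (mean/dispersion parameterization;
``var = mu + dispersion * mu**2``) around sample-scaled means to mimic the
high sampling variance of shallow transcriptome sequencing. Setting
``dispersion=0`` switches sampling off entirely and returns the exact
expected values — the noise-free mode used by exactness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, QpcrPlate, validate_annotation, validate_orthology
from .errors import ConfigurationError

DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 18))


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigurationError(message)


@dataclass
class SimulationConfig:
    """Parameters of the RNA-seq expression simulator.

    Defaults correspond to the shallow-coverage study design the package is
    built around: 4 individuals per sex, 3400 autosomal genes on 17
    autosomes, 150 Z-linked genes, ~6.3 reads per gene and individual, and a
    partial compensation degree of 0.56 (true Z m:f about 1.36).
    """

    n_autosomal_genes: int = 200  # per autosome
    autosome_labels: tuple = DEFAULT_AUTOSOMES
    n_z_genes: int = 150
    n_males: int = 4
    n_females: int = 4
    compensation_degree: float = 0.56
    baseline_log2_expression_mean: float = 3.0
    baseline_log2_expression_sd: float = 1.5
    dispersion: float = 0.15
    mean_reads_per_gene: float = 6.3
    gc_effect_slope_male: float = 0.0
    gc_effect_slope_female: float = 0.0
    z_gc_offset: float = -0.05  # Z chromosomes are relatively GC-poor
    gene_spacing_bp: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_autosomal_genes >= 1, "n_autosomal_genes must be >= 1")
        _require(len(self.autosome_labels) >= 1, "autosome_labels must be non-empty")
        _require(self.n_z_genes >= 1, "n_z_genes must be >= 1")
        _require(self.n_males >= 1, "n_males must be >= 1")
        _require(self.n_females >= 1, "n_females must be >= 1")
        _require(0.0 <= self.compensation_degree <= 1.0, "compensation_degree must lie in [0, 1]")
        _require(self.dispersion >= 0.0, "dispersion must be >= 0")
        _require(self.mean_reads_per_gene > 0.0, "mean_reads_per_gene must be > 0")
        _require(self.baseline_log2_expression_sd >= 0.0, "baseline_log2_expression_sd must be >= 0")


def simulate_expression(config: SimulationConfig):
    """Simulate an annotated two-sex read-count matrix with known ground truth.

    Returns
    -------
    annotation : DataFrame
        Indexed by gene id: chromosome, position_bp, gc_fraction,
        exon_length_bp.
    expr : ExpressionMatrix
        Integer counts (floats in the noise-free ``dispersion=0`` mode), with
        a sample sheet carrying sex, group and library size. Sequencing effort
        is equal across samples by design; the sample sheet records that
        nominal depth.
    truth : DataFrame
        Per-gene ground truth, ``truth_``-prefixed columns: chromosome, log2
        m:f, GC fraction, baseline log2 expression.
    """
    rng = np.random.default_rng(config.seed)
    d = config.compensation_degree

    chroms = [lab for lab in config.autosome_labels for _ in range(config.n_autosomal_genes)]
    chroms += ["Z"] * config.n_z_genes
    chroms = np.asarray(chroms, dtype=object)
    n_genes = len(chroms)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(1, n_genes + 1)], name="gene_id")
    is_z = chroms == "Z"

    gc = rng.uniform(0.35, 0.65, size=n_genes)
    gc[is_z] = np.clip(gc[is_z] + config.z_gc_offset, 0.0, 1.0)
    exon_length = np.round(np.exp(rng.normal(np.log(1500.0), 0.5, size=n_genes))).astype(int)
    exon_length = np.maximum(exon_length, 100)
    position = np.empty(n_genes, dtype=int)
    for lab in list(config.autosome_labels) + ["Z"]:
        mask = chroms == lab
        position[mask] = (np.arange(mask.sum()) + 1) * config.gene_spacing_bp

    base_log2 = rng.normal(
        config.baseline_log2_expression_mean, config.baseline_log2_expression_sd, size=n_genes
    )

    # per-sex log2 output: Z males keep the two-copy baseline, Z females are
    # scaled to 2**d of a single copy => log2 m:f = 1 - d on the Z
    rel_m = np.exp2(base_log2 + config.gc_effect_slope_male * (gc - 0.5))
    # female dose applied multiplicatively so the noise-free m:f is exact
    dose_f = np.where(is_z, 2.0 ** (d - 1.0), 1.0)
    rel_f = np.exp2(base_log2 + config.gc_effect_slope_female * (gc - 0.5)) * dose_f
    # common depth factor so that grand-mean reads/gene/individual hits target
    scale = config.mean_reads_per_gene * n_genes / np.mean([rel_m.sum(), rel_f.sum()])
    mu = {"M": scale * rel_m, "F": scale * rel_f}

    sample_ids, sexes = [], []
    columns = {}
    for sex, n in (("M", config.n_males), ("F", config.n_females)):
        for i in range(1, n + 1):
            sid = f"{sex}{i}"
            sample_ids.append(sid)
            sexes.append(sex)
            columns[sid] = _draw_counts(rng, mu[sex], config.dispersion)

    values = pd.DataFrame(columns, index=gene_ids)
    library_size = int(round(config.mean_reads_per_gene * n_genes))  # nominal equal depth
    samples = pd.DataFrame(
        {
            "sex": sexes,
            "group": "sim",
            "library_size": library_size,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    annotation = validate_annotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": chroms,
                "position_bp": position,
                "gc_fraction": gc,
                "exon_length_bp": exon_length,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "truth_chromosome": chroms,
            "truth_log2_mf": np.where(is_z, 1.0 - d, 0.0),
            "truth_gc_fraction": gc,
            "truth_base_log2_expression": base_log2,
        },
        index=gene_ids,
    )
    expr = ExpressionMatrix(values, samples, unit="counts")
    return annotation, expr, truth


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = mu + dispersion * mu**2.

    dispersion == 0 returns the exact means (deterministic, noise-free mode).
    """
    if dispersion == 0.0:
        return mu.copy()
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# qPCR plate simulator


@dataclass
class QpcrSimConfig:
    """Parameters of the genomic qPCR copy-number plate simulator.

    Template copy number is 2 for autosomal genes in both sexes and for Z
    genes in ZZ males, and 1 for Z genes in ZW females. Per replicate,
    ``Ct = base - log_(1+efficiency)(copies) + sample offset + noise``; the
    autosomal control gene on the same sample cancels base and offset in the
    delta-Ct step.
    """

    n_z_genes: int = 20
    n_autosomal_genes: int = 3  # includes the control gene
    n_males: int = 4
    n_females: int = 4
    replicates: int = 3
    ct_noise_sd: float = 0.15
    sample_offset_sd: float = 0.0  # optional template-loading variation (cancels in delta-Ct)
    efficiency: float = 1.0
    control_gene_id: str = "AUT01"
    template_ng: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_z_genes >= 1, "n_z_genes must be >= 1")
        _require(self.n_autosomal_genes >= 1, "n_autosomal_genes must be >= 1")
        _require(self.n_males >= 1 and self.n_females >= 1, "need at least one sample per sex")
        _require(self.replicates >= 2, "replicates must be >= 2")
        _require(self.ct_noise_sd >= 0.0, "ct_noise_sd must be >= 0")
        _require(self.sample_offset_sd >= 0.0, "sample_offset_sd must be >= 0")
        _require(0.8 < self.efficiency <= 1.1, "efficiency must lie in (0.8, 1.1]")
        autosomal = [f"AUT{i:02d}" for i in range(1, self.n_autosomal_genes + 1)]
        if self.control_gene_id not in autosomal:
            raise ConfigurationError(
                f"control_gene_id {self.control_gene_id!r} is not among the autosomal genes {autosomal}"
            )


def simulate_qpcr(config: QpcrSimConfig) -> QpcrPlate:
    """Simulate a replicate-level qPCR plate with known Z/autosome truth."""
    rng = np.random.default_rng(config.seed)

    genes = [(f"Z{i:02d}", "Z") for i in range(1, config.n_z_genes + 1)]
    genes += [(f"AUT{i:02d}", "autosome") for i in range(1, config.n_autosomal_genes + 1)]
    base_ct = {gid: rng.uniform(20.0, 26.0) for gid, _ in genes}

    samples = [(f"M{i}", "M") for i in range(1, config.n_males + 1)]
    samples += [(f"F{i}", "F") for i in range(1, config.n_females + 1)]
    sample_offset = {
        sid: (rng.normal(0.0, config.sample_offset_sd) if config.sample_offset_sd > 0 else 0.0)
        for sid, _ in samples
    }

    log_base = np.log(1.0 + config.efficiency)
    rows = []
    for sid, sex in samples:
        for gid, linkage in genes:
            copies = 1.0 if (linkage == "Z" and sex == "F") else 2.0
            center = base_ct[gid] - np.log(copies) / log_base + sample_offset[sid]
            cts = center + rng.normal(0.0, config.ct_noise_sd, size=config.replicates)
            for rep, ct in enumerate(cts, start=1):
                rows.append((sid, sex, "sim", gid, "exon1", config.template_ng, rep, ct))

    records = pd.DataFrame(
        rows,
        columns=["sample_id", "sex", "group", "gene_id", "locus", "template_ng", "replicate", "ct"],
    )
    truth = pd.DataFrame(
        {"gene_id": [g for g, _ in genes], "truth_linkage": [l for _, l in genes]}
    )
    return QpcrPlate(records, truth=truth)


# ---------------------------------------------------------------------------
# orthology simulator


def simulate_orthology(
    n_genes: int,
    disruption_rate: float,
    seed: int,
    chromosomes: tuple = DEFAULT_AUTOSOMES + ("Z",),
    gene_ids=None,
    reference_chromosomes=None,
) -> pd.DataFrame:
    """Simulate a 1:1 orthology map with a known synteny-disruption rate.

    Each focal gene sits on the chromosome its reference orthologue occupies,
    except a Bernoulli(``disruption_rate``) fraction that has moved to a
    uniformly chosen *different* chromosome. The returned frame carries the
    standard orthology columns plus ``truth_focal_chromosome`` and
    ``truth_disrupted``.

    ``gene_ids`` / ``reference_chromosomes`` let the caller align the map with
    an existing annotation; by default genes are spread over ``chromosomes``
    round-robin.
    """
    if not 0.0 <= disruption_rate < 1.0:
        raise ConfigurationError("disruption_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    chromosomes = [str(c) for c in chromosomes]

    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    gene_ids = list(gene_ids)
    if reference_chromosomes is None:
        reference_chromosomes = [chromosomes[i % len(chromosomes)] for i in range(len(gene_ids))]
    ref_chrom = np.asarray([str(c) for c in reference_chromosomes], dtype=object)

    disrupted = rng.random(len(gene_ids)) < disruption_rate
    focal_chrom = ref_chrom.copy()
    for i in np.flatnonzero(disrupted):
        others = [c for c in chromosomes if c != ref_chrom[i]]
        focal_chrom[i] = others[rng.integers(len(others))]

    return validate_orthology(
        pd.DataFrame(
            {
                "focal_gene_id": gene_ids,
                "reference_gene_id": [f"REF_{g}" for g in gene_ids],
                "reference_chromosome": ref_chrom,
                "relationship": "one2one",
                "truth_focal_chromosome": focal_chrom,
                "truth_disrupted": disrupted,
            }
        )
    )


# ---------------------------------------------------------------------------
# file output helpers (sidecar ground truth uses the truth_ prefix)


def write_simulated_expression(annotation, expr, truth, outdir) -> dict:
    """Write annotation/counts/samples/truth TSVs into ``outdir``; return paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth_genes.tsv",
    }
    from .containers import write_annotation

    write_annotation(annotation, paths["annotation"])
    expr.to_tsv(paths["counts"], paths["samples"])
    truth.to_csv(paths["truth"], sep="\t")
    return paths
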
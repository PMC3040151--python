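"""Read-count normalization, chromosome assignment and core gene-set filtering.

RPKM (reads per kilobase of exon model per million mapped reads) is the
digital expression measure used throughout:

    RPKM_{g,s} = 1e9 * C_{g,s} / (N_s * L_g)

with ``C`` the read count, ``N_s`` the sample's library size and ``L_g`` the
gene's exon length in bp.

Chromosome identity of a focal-species gene is transferred from a reference
species over 1:1 orthology; genes without a one-to-one orthologue are dropped
(and counted), since paralogy makes both the chromosome label and the
expression assignment ambiguous.

The core gene-set filter removes genes whose shallow coverage makes per-sex
mean expression unstable: a gene is kept only if its RPKM exceeds the
individual's own mean RPKM (across all genes) in at least ``min_samples_per_sex``
males *and* females, and if |log2(m:f)| does not exceed ``log2_mf_bound``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, make_mf_table, validate_annotation, validate_orthology
from .errors import InputError

logger = logging.getLogger(__name__)


def compute_rpkm(counts: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Convert a count matrix to RPKM using library sizes and exon lengths."""
    if counts.unit != "counts":
        raise InputError(f"expected a count matrix, got unit={counts.unit!r}")
    annotation = validate_annotation(annotation)
    if "library_size" not in counts.samples.columns:
        raise InputError("sample sheet has no library_size column")

    missing = counts.gene_ids.difference(annotation.index)
    if len(missing):
        raise InputError(f"no annotation for genes: {list(missing[:5])}")

    lib = counts.samples["library_size"].astype(float)
    bad_lib = lib.index[~(lib > 0)]
    if len(bad_lib):
        raise InputError(f"non-positive library size for sample {bad_lib[0]!r}")
    length = annotation.loc[counts.gene_ids, "exon_length_bp"].astype(float)
    bad_len = length.index[~(length > 0)]
    if len(bad_len):
        raise InputError(f"non-positive exon length for gene {bad_len[0]!r}")

    rpkm = counts.values.div(lib, axis=1).div(length, axis=0) * 1e9
    return ExpressionMatrix(rpkm, counts.samples.copy(), unit="rpkm")


def assign_chromosomes(expr: ExpressionMatrix, orthology: pd.DataFrame):
    """Attach reference-species chromosome labels over 1:1 orthology.

    Returns ``(expr_subset, chromosomes, n_dropped)`` where ``chromosomes`` is
    a Series indexed by retained gene id. Genes without a one2one orthologue
    are dropped and counted.
    """
    orthology = validate_orthology(orthology)
    one2one = orthology.loc[orthology["relationship"] == "one2one"]
    if one2one["focal_gene_id"].duplicated().any():
        dup = one2one.loc[one2one["focal_gene_id"].duplicated(), "focal_gene_id"].iloc[0]
        raise InputError(f"duplicate focal gene id in one2one orthology: {dup!r}")
    if one2one["reference_gene_id"].duplicated().any():
        dup = one2one.loc[one2one["reference_gene_id"].duplicated(), "reference_gene_id"].iloc[0]
        raise InputError(f"duplicate reference gene id in one2one orthology: {dup!r}")

    mapping = one2one.set_index("focal_gene_id")["reference_chromosome"]
    retained = expr.gene_ids.intersection(mapping.index)
    n_dropped = expr.n_genes - len(retained)
    if len(retained) == 0:
        logger.warning("no genes with one2one orthologues; result is empty")
        empty = ExpressionMatrix(expr.values.iloc[:0], expr.samples.copy(), expr.unit)
        return empty, pd.Series(dtype=object, name="chromosome"), n_dropped
    if n_dropped:
        logger.info("dropped %d genes without a one2one orthologue", n_dropped)
    subset = expr.subset_genes(retained)
    chromosomes = mapping.loc[retained].rename("chromosome")
    chromosomes.index.name = "gene_id"
    return subset, chromosomes, n_dropped


def filter_core_gene_set(
    expr: ExpressionMatrix,
    chromosomes: pd.Series,
    min_samples_per_sex: int = 2,
    log2_mf_bound: float = 4.0,
    threshold: str = "per_individual",
):
    """Apply the core gene-set filter and build the per-gene m:f table.

    Parameters
    ----------
    expr : ExpressionMatrix
        RPKM matrix.
    chromosomes : Series
        Chromosome label per gene id (from :func:`assign_chromosomes` or an
        annotation table).
    min_samples_per_sex : int
        Minimum number of males and of females in which the gene must exceed
        the expression threshold.
    log2_mf_bound : float
        Genes with |log2(m:f)| above this bound are discarded as artefacts of
        near-zero coverage in one sex.
    threshold : str
        ``"per_individual"`` (default) compares each gene against that
        individual's own mean RPKM over all genes; ``"global"`` uses the grand
        mean RPKM of the whole matrix instead.

    Returns
    -------
    (ExpressionMatrix subset, m:f table DataFrame)
    """
    if expr.unit != "rpkm":
        raise InputError(f"core gene-set filter expects RPKM, got unit={expr.unit!r}")
    males, females = expr.sample_ids("M"), expr.sample_ids("F")
    if not males or not females:
        raise InputError("both sexes must be present in the sample sheet")
    if threshold == "per_individual":
        cutoff = expr.values.mean(axis=0)  # one mean per individual
    elif threshold == "global":
        cutoff = pd.Series(expr.values.to_numpy().mean(), index=expr.values.columns)
    else:
        raise InputError(f"unknown threshold mode {threshold!r}")

    above = expr.values.gt(cutoff, axis=1)
    expressed = (above[males].sum(axis=1) >= min_samples_per_sex) & (
        above[females].sum(axis=1) >= min_samples_per_sex
    )
    subset = expr.subset_genes(expr.gene_ids[expressed])

    mf = make_mf_table(subset, chromosomes)
    mf = mf.loc[mf["log2_mf"].abs() <= log2_mf_bound].reset_index(drop=True)
    subset = subset.subset_genes(pd.Index(mf["gene_id"]))
    return subset, mf


def annotation_chromosomes(annotation: pd.DataFrame) -> pd.Series:
    """Chromosome labels straight from an annotation table (no orthology)."""
    annotation = validate_annotation(annotation)
    s = annotation["chromosome"].copy()
    s.index.name = "gene_id"
    return s
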
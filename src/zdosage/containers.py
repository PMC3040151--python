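"""Core data containers and plain-text I/O.

The analysis passes around four tabular objects:

* a gene annotation table (chromosome, GC fraction, exon length, optional
  position) keyed by gene id,
* an :class:`ExpressionMatrix` — genes x samples counts or RPKM plus a sample
  sheet with sex labels and library sizes,
* an m:f table — per-gene sex means, male-to-female ratio and log2 ratio,
* a :class:`QpcrPlate` — replicate Ct values per (sample, gene, locus).

All files are tab-separated text except the qPCR plate, which follows the
comma-separated export convention of qPCR instruments (one row per reaction
well group, replicate Ct values in ``ct1..ctK`` columns, blank = missing).
Missing values in TSV inputs are written as ``.``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "position_bp", "gc_fraction", "exon_length_bp"]
ORTHOLOGY_COLUMNS = ["focal_gene_id", "reference_gene_id", "reference_chromosome", "relationship"]
SEXES = ("M", "F")
NA_TOKEN = "."


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a sample sheet.

    Parameters
    ----------
    values : DataFrame
        Non-negative expression values, index = gene ids, columns = sample ids.
    samples : DataFrame
        Sample sheet indexed by sample id with columns ``sex`` (``M``/``F``),
        ``group`` (free label, e.g. population or colour morph) and
        ``library_size`` (total mapped reads of the sample).
    unit : str
        Either ``"counts"`` or ``"rpkm"``; downstream steps check this flag.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "rpkm"):
            raise InputError(f"unit must be 'counts' or 'rpkm', got {self.unit!r}")
        missing = [s for s in self.samples.index if s not in self.values.columns]
        if missing:
            raise InputError(f"samples missing from the value matrix: {missing}")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise InputError(f"sex labels must be in {SEXES}, found {sorted(bad_sex)}")
        if (self.values.to_numpy() < 0).any():
            raise InputError("expression values must be non-negative")
        # keep value columns aligned with (and restricted to) the sheet
        self.values = self.values.loc[:, list(self.samples.index)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def sample_ids(self, sex: str | None = None) -> list[str]:
        if sex is None:
            return list(self.samples.index)
        if sex not in SEXES:
            raise InputError(f"sex must be one of {SEXES}, got {sex!r}")
        return list(self.samples.index[self.samples["sex"] == sex])

    def sex_means(self) -> pd.DataFrame:
        """Per-gene mean expression in each sex (columns ``mean_m``, ``mean_f``)."""
        males, females = self.sample_ids("M"), self.sample_ids("F")
        if not males or not females:
            raise InputError("both sexes must be present in the sample sheet")
        return pd.DataFrame(
            {
                "mean_m": self.values[males].mean(axis=1),
                "mean_f": self.values[females].mean(axis=1),
            }
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.samples.copy(), self.unit)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, values_path, samples_path, unit: str = "counts") -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id", na_values=[NA_TOKEN])
        samples = read_sample_sheet(samples_path)
        return cls(values, samples, unit)

    def to_tsv(self, values_path, samples_path=None) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(values_path, sep="\t", na_rep=NA_TOKEN)
        if samples_path is not None:
            sheet = self.samples.copy()
            sheet.index.name = "sample_id"
            sheet.to_csv(samples_path, sep="\t", na_rep=NA_TOKEN)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    required = {"sample_id", "sex"}
    if not required.issubset(sheet.columns):
        raise InputError(f"sample sheet must contain columns {sorted(required)}")
    if "group" not in sheet.columns:
        sheet["group"] = "all"
    if sheet["sample_id"].duplicated().any():
        raise InputError("duplicate sample ids in the sample sheet")
    return sheet.set_index("sample_id")


# ---------------------------------------------------------------------------
# gene annotation


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table and return it indexed by gene id.

    ``position_bp`` may be missing (all-NA column is fine); GC fractions must
    lie in [0, 1] and exon lengths must be at least 1 bp.
    """
    df = annotation.reset_index() if annotation.index.name == "gene_id" else annotation.copy()
    missing = [c for c in ("gene_id", "chromosome", "gc_fraction", "exon_length_bp") if c not in df.columns]
    if missing:
        raise InputError(f"annotation is missing columns {missing}")
    if "position_bp" not in df.columns:
        df["position_bp"] = np.nan
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputError(f"duplicate gene id in annotation: {dup!r}")
    gc = df["gc_fraction"].astype(float)
    if ((gc < 0) | (gc > 1)).any():
        raise InputError("gc_fraction must lie in [0, 1]")
    if (df["exon_length_bp"].astype(float) < 1).any():
        raise InputError("exon_length_bp must be >= 1")
    df["chromosome"] = df["chromosome"].astype(str)
    return df.set_index("gene_id")


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t", na_values=[NA_TOKEN]))


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# orthology map


def validate_orthology(orthology: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ORTHOLOGY_COLUMNS if c not in orthology.columns]
    if missing:
        raise InputError(f"orthology map is missing columns {missing}")
    df = orthology.copy()
    df["reference_chromosome"] = df["reference_chromosome"].astype(str)
    return df


def read_orthology(path) -> pd.DataFrame:
    return validate_orthology(pd.read_csv(path, sep="\t", na_values=[NA_TOKEN]))


def write_orthology(orthology: pd.DataFrame, path) -> None:
    orthology.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# m:f table


MF_COLUMNS = ["gene_id", "chromosome", "mean_m", "mean_f", "mf_ratio", "log2_mf"]


def make_mf_table(expr: ExpressionMatrix, chromosomes: pd.Series) -> pd.DataFrame:
    """Build the per-gene m:f table from an RPKM matrix.

    The ratio is the ratio of per-sex means (not the mean of per-individual
    ratios). Genes with a zero mean in either sex have no finite log2 ratio
    and are dropped.
    """
    means = expr.sex_means()
    df = means.join(chromosomes.rename("chromosome"), how="inner")
    keep = (df["mean_m"] > 0) & (df["mean_f"] > 0)
    df = df.loc[keep].copy()
    df["mf_ratio"] = df["mean_m"] / df["mean_f"]
    df["log2_mf"] = np.log2(df["mf_ratio"])
    df.index.name = "gene_id"
    return df.reset_index()[MF_COLUMNS]


def write_mf_table(mf_table: pd.DataFrame, path) -> None:
    mf_table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_mf_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    missing = [c for c in MF_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"m:f table is missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# qPCR plate


@dataclass
class QpcrPlate:
    """Long-format qPCR plate: one row per replicate Ct measurement.

    Columns: ``sample_id``, ``sex``, ``group``, ``gene_id``, ``locus``,
    ``template_ng``, ``replicate`` (1-based), ``ct``.
    """

    records: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    REQUIRED = ["sample_id", "sex", "gene_id", "locus", "replicate", "ct"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise InputError(f"qPCR plate is missing columns {missing}")
        bad_sex = set(self.records["sex"]) - set(SEXES)
        if bad_sex:
            raise InputError(f"sex labels must be in {SEXES}, found {sorted(bad_sex)}")
        counts = self.records.groupby(["sample_id", "gene_id", "locus"])["ct"].count()
        if (counts < 2).any():
            offender = counts[counts < 2].index[0]
            raise InputError(f"fewer than 2 replicate Ct values for {offender}")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.records["gene_id"].unique())

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct per (sample, sex, gene, locus)."""
        return (
            self.records.groupby(["sample_id", "sex", "gene_id", "locus"], as_index=False)["ct"]
            .mean()
            .rename(columns={"ct": "mean_ct"})
        )

    @classmethod
    def read_csv(cls, path) -> "QpcrPlate":
        wide = pd.read_csv(path)
        return cls(melt_plate(wide))

    def to_csv(self, path) -> None:
        """Write the plate back out in the wide one-row-per-well-group dialect."""
        wide = pivot_plate(self.records)
        wide.to_csv(path, index=False)


def melt_plate(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide plate CSV (``ct1``, ``ct2``, ... columns) to long format."""
    ct_cols = [c for c in wide.columns if c.startswith("ct") and c[2:].isdigit()]
    if not ct_cols:
        raise InputError("plate CSV has no ct1..ctK replicate columns")
    id_cols = [c for c in wide.columns if c not in ct_cols]
    long = wide.melt(id_vars=id_cols, value_vars=ct_cols, var_name="replicate", value_name="ct")
    long["replicate"] = long["replicate"].str[2:].astype(int)
    long = long.dropna(subset=["ct"]).reset_index(drop=True)
    if "group" not in long.columns:
        long["group"] = "all"
    if "template_ng" not in long.columns:
        long["template_ng"] = np.nan
    return long


def pivot_plate(records: pd.DataFrame) -> pd.DataFrame:
    keys = ["sample_id", "sex", "group", "gene_id", "locus", "template_ng"]
    keys = [k for k in keys if k in records.columns]
    wide = records.pivot_table(index=keys, columns="replicate", values="ct", dropna=False)
    wide.columns = [f"ct{int(c)}" for c in wide.columns]
    return wide.reset_index()
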
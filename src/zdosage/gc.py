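"""Estimation and removal of the GC-content effect on expression ratios.

Library PCR during sequencing amplifies GC-intermediate fragments more
efficiently, so per-gene expression estimates — and, when the bias differs
between the sexes' libraries, the m:f ratio — carry a GC-dependent component.
Because GC content differs systematically between chromosome classes (micro-
vs macro-chromosomes, and a relatively GC-poor Z), an uncorrected GC bias
masquerades as between-chromosome differences in m:f. The fix is a linear
residualization: regress the quantity on GC fraction by ordinary least
squares and keep residuals re-centred on the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError, InputError


@dataclass(frozen=True)
class GcModel:
    """OLS fit of a per-gene response on GC fraction.

    slope is in log2 units per unit GC fraction; the F statistic tests the
    slope against zero (equivalent to the squared slope t statistic).
    """

    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    n: int

    def predict(self, gc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(gc, dtype=float)


def fit_gc_effect(response, gc) -> GcModel:
    """OLS of a per-gene response (log2 expression or log2 m:f) on GC fraction."""
    response = np.asarray(response, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if response.shape != gc.shape:
        raise InputError("response and gc must have the same length")
    ok = np.isfinite(response) & np.isfinite(gc)
    response, gc = response[ok], gc[ok]
    if len(response) < 3:
        raise InputError(f"need at least 3 paired finite values, got {len(response)}")
    if np.ptp(gc) == 0.0:
        raise DegenerateDesignError("gc fraction is constant; the slope is unidentifiable")

    fit = sm.OLS(response, sm.add_constant(gc)).fit()
    return GcModel(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        n=int(fit.nobs),
    )


def remove_gc_effect(mf_table: pd.DataFrame, annotation: pd.DataFrame):
    """Residualize log2(m:f) on GC fraction, preserving the grand mean.

    Genes without a GC value are dropped (and counted). The returned table
    keeps the uncorrected column as ``log2_mf_raw`` and adds
    ``log2_mf_gc_adjusted`` (which also replaces ``log2_mf`` so that
    downstream chromosome inference consumes the corrected values) plus the
    ``gc_fraction`` used.

    Returns
    -------
    (adjusted m:f table, GcModel, n_dropped)
    """
    ann = annotation if annotation.index.name == "gene_id" else annotation.set_index("gene_id")
    df = mf_table.copy()
    df["gc_fraction"] = df["gene_id"].map(ann["gc_fraction"]).astype(float)
    n_dropped = int(df["gc_fraction"].isna().sum())
    df = df.dropna(subset=["gc_fraction"]).reset_index(drop=True)

    base = df["log2_mf_raw"] if "log2_mf_raw" in df.columns else df["log2_mf"]
    model = fit_gc_effect(base.to_numpy(), df["gc_fraction"].to_numpy())
    residual = base.to_numpy() - model.predict(df["gc_fraction"])
    adjusted = residual + base.mean()

    df["log2_mf_raw"] = base
    df["log2_mf_gc_adjusted"] = adjusted
    df["log2_mf"] = adjusted
    df["mf_ratio"] = 2.0 ** df["log2_mf"]
    return df, model, n_dropped


def sex_specific_gc_fits(expr, annotation: pd.DataFrame) -> dict:
    """GC effect on mean log2 expression per sex (reporting/QC only).

    Genes with a zero mean in a sex are excluded from that sex's fit.
    """
    ann = annotation if annotation.index.name == "gene_id" else annotation.set_index("gene_id")
    means = expr.sex_means()
    gc = ann.loc[means.index, "gc_fraction"].to_numpy(dtype=float)
    out = {}
    for sex, col in (("M", "mean_m"), ("F", "mean_f")):
        vals = means[col].to_numpy(dtype=float)
        ok = vals > 0
        out[sex] = fit_gc_effect(np.log2(vals[ok]), gc[ok])
    return out
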
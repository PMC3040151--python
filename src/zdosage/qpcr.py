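"""Z-linkage verification from genomic qPCR copy-number assays.

In a ZZ/ZW species the genomic copy number of a Z-linked locus is 2 in males
and 1 in females, while autosomal loci carry 2 copies in both sexes. After
delta-Ct normalization to an autosomal control gene the expected
male:female ratio of relative template concentration is therefore 2 for a
Z-linked locus and 1 for an autosomal one — a clean decision rule even when
amplification efficiencies shift the absolute concentrations away from the
ideal 1 (male) and 0.5 (female).

The module provides the per-locus statistics (ΔCt concentrations, pooled
one-sided t test of male > female), the gene-level Z/autosome caller, control
gene ranking, standard-curve amplification efficiency, an exact test for
excess synteny disruption, and the intron-length consistency regression used
to show that a discordant gene moved intact rather than retrotransposed.

:data:`CROW_QPCR_TABLE` loads a bundled published worked example: 21
candidate Z-linked crow genes assayed at 1–6 primer pairs each (one Ensembl
id appears as two independently assayed candidate entries), normalized to an
autosomal control, with per-locus mean concentrations, m:f ratio, t and
one-sided p at df = 6 (4 males vs 4 females).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QpcrPlate
from .errors import InputError

__all__ = [
    "LocusResult",
    "ZlinkCall",
    "delta_ct_concentration",
    "sample_concentrations",
    "locus_mf_test",
    "plate_locus_results",
    "call_z_linkage",
    "call_z_linkage_from_results",
    "choose_control_gene",
    "efficiency_from_dilution",
    "synteny_disruption_test",
    "hypergeom_fisher_oracle",
    "intron_length_check",
    "load_crow_qpcr_table",
    "ZlinkageQpcrModel",
    "ZlinkageQpcrResults",
]


@dataclass(frozen=True)
class LocusResult:
    gene_id: str
    locus: str
    mean_conc_f: float
    mean_conc_m: float
    mf_ratio: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class ZlinkCall:
    gene_id: str
    call: str  # Z_linked | autosomal | ambiguous
    n_loci: int


def delta_ct_concentration(ct_target, ct_control):
    """Relative concentration 2**-(Ct_target - Ct_control), elementwise."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_control = np.asarray(ct_control, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_control).all()):
        raise InputError("Ct values must be finite")
    out = 2.0 ** -(ct_target - ct_control)
    return float(out) if out.ndim == 0 else out


def sample_concentrations(plate: QpcrPlate, control_gene_id: str) -> pd.DataFrame:
    """Per-sample relative concentrations of every non-control (gene, locus).

    Replicate Ct values are averaged per (sample, gene, locus) first; each
    target is then normalized to the control gene measured on the same sample.
    """
    mean_ct = plate.mean_ct()
    control = mean_ct.loc[mean_ct["gene_id"] == control_gene_id]
    if control.empty:
        raise InputError(f"control gene {control_gene_id!r} not on the plate")
    control_ct = control.groupby("sample_id")["mean_ct"].mean()

    targets = mean_ct.loc[mean_ct["gene_id"] != control_gene_id].copy()
    missing = set(targets["sample_id"]) - set(control_ct.index)
    if missing:
        raise InputError(
            f"control gene {control_gene_id!r} missing for samples {sorted(missing)}"
        )
    targets["concentration"] = delta_ct_concentration(
        targets["mean_ct"].to_numpy(),
        control_ct.loc[targets["sample_id"]].to_numpy(),
    )
    return targets[["sample_id", "sex", "gene_id", "locus", "concentration"]]


def locus_mf_test(conc_m, conc_f, gene_id: str = "", locus: str = "") -> LocusResult:
    """Pooled two-sample t test of male vs female relative concentration.

    One-sided p for the alternative male > female (the Z-linkage direction);
    df = n_m + n_f - 2. Zero variance in both groups with equal means gives
    t = 0, p = 0.5 (the one-sided null centre).
    """
    conc_m = np.asarray(conc_m, dtype=float)
    conc_f = np.asarray(conc_f, dtype=float)
    n_m, n_f = len(conc_m), len(conc_f)
    if n_m < 2 or n_f < 2:
        raise InputError("need at least 2 samples per sex")
    df = n_m + n_f - 2
    mean_m, mean_f = conc_m.mean(), conc_f.mean()
    pooled_var = ((n_m - 1) * conc_m.var(ddof=1) + (n_f - 1) * conc_f.var(ddof=1)) / df
    se = np.sqrt(pooled_var * (1.0 / n_m + 1.0 / n_f))
    if se == 0.0:
        t_stat = 0.0 if mean_m == mean_f else np.inf * np.sign(mean_m - mean_f)
    else:
        t_stat = (mean_m - mean_f) / se
    p = float(stats.t.sf(t_stat, df)) if np.isfinite(t_stat) else (0.0 if t_stat > 0 else 1.0)
    if t_stat == 0.0:
        p = 0.5
    return LocusResult(
        gene_id=gene_id,
        locus=locus,
        mean_conc_f=float(mean_f),
        mean_conc_m=float(mean_m),
        mf_ratio=float(mean_m / mean_f) if mean_f != 0 else np.inf,
        t=float(t_stat),
        df=df,
        p=p,
    )


def plate_locus_results(plate: QpcrPlate, control_gene_id: str) -> pd.DataFrame:
    """Run the ΔCt + t-test pipeline for every (gene, locus) on a plate."""
    conc = sample_concentrations(plate, control_gene_id)
    rows = []
    for (gene_id, locus), grp in conc.groupby(["gene_id", "locus"], sort=True):
        res = locus_mf_test(
            grp.loc[grp["sex"] == "M", "concentration"].to_numpy(),
            grp.loc[grp["sex"] == "F", "concentration"].to_numpy(),
            gene_id=gene_id,
            locus=locus,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def call_z_linkage(loci, alpha: float = 0.05, ratio_boundary: float = 1.5) -> ZlinkCall:
    """Combine one gene's locus results into a Z/autosome call.

    Z_linked iff every locus shows p < alpha *and* m:f at or above the
    boundary (default 1.5, the linear midpoint between the autosomal
    expectation 1 and the Z expectation 2); autosomal iff every locus is
    below the boundary with p >= alpha; conflicting loci give ``ambiguous``.
    """
    loci = list(loci)
    if not loci:
        raise InputError("need at least one locus result")
    gene_id = loci[0].gene_id
    z_like = all(l.p < alpha and l.mf_ratio >= ratio_boundary for l in loci)
    a_like = all(l.p >= alpha and l.mf_ratio < ratio_boundary for l in loci)
    call = "Z_linked" if z_like else ("autosomal" if a_like else "ambiguous")
    return ZlinkCall(gene_id=gene_id, call=call, n_loci=len(loci))


def call_z_linkage_from_results(
    locus_results: pd.DataFrame,
    alpha: float = 0.05,
    ratio_boundary: float = 1.5,
    group_col: str = "gene_id",
) -> pd.DataFrame:
    """Gene-level calls from a locus-result table (one row per locus)."""
    calls = []
    for gene_id, grp in locus_results.groupby(group_col, sort=True):
        loci = [
            LocusResult(
                gene_id=str(gene_id),
                locus=str(r.get("locus", "")),
                mean_conc_f=float(r.get("mean_conc_f", r.get("conc_f", np.nan))),
                mean_conc_m=float(r.get("mean_conc_m", r.get("conc_m", np.nan))),
                mf_ratio=float(r["mf_ratio"]),
                t=float(r.get("t", np.nan)),
                df=int(r["df"]) if "df" in r and pd.notna(r.get("df")) else 0,
                p=float(r.get("p", r.get("p_value"))),
            )
            for _, r in grp.iterrows()
        ]
        call = call_z_linkage(loci, alpha=alpha, ratio_boundary=ratio_boundary)
        calls.append({"gene_id": gene_id, "call": call.call, "n_loci": call.n_loci})
    return pd.DataFrame(calls)


def choose_control_gene(plate: QpcrPlate, candidate_gene_ids=None) -> pd.DataFrame:
    """Rank candidate normalizer genes.

    A good control behaves autosomally (mean raw-Ct-implied m:f near 1) and
    amplifies consistently (small Ct standard deviation across samples).
    Candidates are ranked by |mean m:f - 1| ascending, ties broken by Ct sd.
    The m:f here is computed from raw mean Ct per sex (2**(Ct_f - Ct_m)),
    since no normalizer exists yet at this stage.
    """
    mean_ct = plate.mean_ct()
    if candidate_gene_ids is None:
        candidate_gene_ids = sorted(mean_ct["gene_id"].unique())
    if len(candidate_gene_ids) < 2:
        raise InputError("need at least 2 candidate control genes")
    rows = []
    for gid in candidate_gene_ids:
        sub = mean_ct.loc[mean_ct["gene_id"] == gid]
        if sub.empty:
            raise InputError(f"candidate {gid!r} not on the plate")
        ct_m = sub.loc[sub["sex"] == "M", "mean_ct"].mean()
        ct_f = sub.loc[sub["sex"] == "F", "mean_ct"].mean()
        mf = 2.0 ** (ct_f - ct_m)  # lower Ct = more template
        rows.append(
            {
                "gene_id": gid,
                "mean_mf": mf,
                "abs_mf_dev": abs(mf - 1.0),
                "ct_sd": sub["mean_ct"].std(ddof=1),
            }
        )
    ranked = pd.DataFrame(rows).sort_values(["abs_mf_dev", "ct_sd"], kind="mergesort")
    return ranked.reset_index(drop=True)


def efficiency_from_dilution(template_ng, ct) -> tuple[float, float]:
    """Amplification efficiency from a serial-dilution standard curve.

    Fits Ct against log10(template) by least squares; efficiency is
    ``10**(-1/slope) - 1`` (1.0 = perfect per-cycle doubling, slope -3.32).
    Requires >= 3 dilution points spanning >= 2 logs and a negative slope.
    Returns ``(efficiency, slope)``.
    """
    template_ng = np.asarray(template_ng, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if len(template_ng) < 3:
        raise InputError("need at least 3 dilution points")
    logt = np.log10(template_ng)
    if np.ptp(logt) < 2.0:
        raise InputError("dilution series must span at least 2 log10 units")
    slope = stats.linregress(logt, ct).slope
    if slope >= 0.0:
        raise InputError(f"non-negative standard-curve slope ({slope:.3f}); more template must lower Ct")
    return 10.0 ** (-1.0 / slope) - 1.0, float(slope)


def synteny_disruption_test(
    observed_moved: int, observed_total: int, background_moved: int, background_total: int
) -> tuple[float, float]:
    """Fisher exact test for excess chromosome movement in a tested gene set.

    2x2 table: [[moved, stayed] in the tested set, [moved, stayed] in the
    background orthologue set]. Returns (one-sided greater, two-sided) p.
    """
    counts = [observed_moved, observed_total, background_moved, background_total]
    if any(c < 0 for c in counts):
        raise InputError("counts must be non-negative")
    if observed_moved > observed_total or background_moved > background_total:
        raise InputError("moved count exceeds total")
    table = [
        [observed_moved, observed_total - observed_moved],
        [background_moved, background_total - background_moved],
    ]
    p_greater = float(stats.fisher_exact(table, alternative="greater").pvalue)
    p_two = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return p_greater, p_two


def hypergeom_fisher_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Brute-force hypergeometric enumeration of the Fisher exact test.

    For the table [[a, b], [c, d]]: enumerate all tables with the same
    margins; one-sided p sums P(X >= a), two-sided sums probabilities
    <= P(observed) (the conventional 'small p' rule). Independent of scipy —
    used as an equivalence oracle in tests.
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: prob(x) for x in range(lo, hi + 1)}
    p_greater = sum(p for x, p in probs.items() if x >= a)
    p_obs = probs[a]
    p_two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    return min(1.0, p_greater), min(1.0, p_two)


def intron_length_check(observed_product_bp, expected_with_intron_bp):
    """Regress observed amplicon lengths on intron-inclusive expectations.

    A slope near 1 with high R² indicates the amplified genomic locus retains
    its introns (whole-gene movement rather than retrotransposition).
    Returns ``(r_squared, p_slope, slope)``.
    """
    obs = np.asarray(observed_product_bp, dtype=float)
    exp = np.asarray(expected_with_intron_bp, dtype=float)
    if len(obs) < 3 or len(obs) != len(exp):
        raise InputError("need >= 3 paired junction lengths")
    fit = stats.linregress(exp, obs)
    return float(fit.rvalue**2), float(fit.pvalue), float(fit.slope)


# ---------------------------------------------------------------------------
# bundled worked example


def load_crow_qpcr_table() -> pd.DataFrame:
    """Published per-locus qPCR results for 21 candidate Z-linked crow genes.

    Columns: candidate (grouping key; one Ensembl id occurs as two
    independent candidate entries), gene_id, locus, primer, conc_f, conc_m
    (mean relative concentration per sex), mf_ratio, t and one-sided p at
    df = 6. Printed concentrations are display values; the ratio column is
    authoritative for calling.
    """
    with resources.files("zdosage.data").joinpath("crow_zlinkage_qpcr.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# model/results wrapper


class ZlinkageQpcrModel:
    """ΔCt Z-linkage analysis of one plate, statsmodels-style.

    ``fit()`` returns a :class:`ZlinkageQpcrResults` holding the per-locus
    statistics and gene-level calls.
    """

    def __init__(self, plate: QpcrPlate, control_gene_id: str):
        self.plate = plate
        self.control_gene_id = control_gene_id

    def fit(self, alpha: float = 0.05, ratio_boundary: float = 1.5) -> "ZlinkageQpcrResults":
        locus_results = plate_locus_results(self.plate, self.control_gene_id)
        calls = call_z_linkage_from_results(
            locus_results, alpha=alpha, ratio_boundary=ratio_boundary
        )
        return ZlinkageQpcrResults(
            locus_results=locus_results,
            calls=calls,
            control_gene_id=self.control_gene_id,
            alpha=alpha,
            ratio_boundary=ratio_boundary,
        )


@dataclass
class ZlinkageQpcrResults:
    locus_results: pd.DataFrame
    calls: pd.DataFrame
    control_gene_id: str
    alpha: float
    ratio_boundary: float

    def summary(self) -> str:
        n = self.calls["call"].value_counts()
        lines = [
            f"Z-linkage calls from ΔCt qPCR (control: {self.control_gene_id}, "
            f"alpha={self.alpha}, ratio boundary={self.ratio_boundary})",
            f"genes: {len(self.calls)}  Z_linked: {n.get('Z_linked', 0)}  "
            f"autosomal: {n.get('autosomal', 0)}  ambiguous: {n.get('ambiguous', 0)}",
            "",
            f"{'gene':<12} {'locus':<8} {'f':>6} {'m':>6} {'m:f':>6} {'t':>7} {'p':>9}",
        ]
        for _, r in self.locus_results.iterrows():
            lines.append(
                f"{r['gene_id']:<12} {r['locus']:<8} {r['mean_conc_f']:>6.2f} "
                f"{r['mean_conc_m']:>6.2f} {r['mf_ratio']:>6.2f} {r['t']:>7.2f} {r['p']:>9.5f}"
            )
        return "\n".join(lines)
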
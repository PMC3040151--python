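"""Chromosome-level dosage-compensation inference.

The central quantity is the per-gene log2 male:female expression ratio.
Under full dosage compensation its expectation is 0 on every chromosome;
with no compensation it is 1 (ratio 2) on the Z and 0 on autosomes. The
chromosome-level estimate is a linear regression of log2(m:f) on chromosome
identity with the intercept dropped, so each coefficient is that
chromosome's mean log2 ratio and the regression F statistic tests the joint
null that all chromosome means are zero. Confidence intervals are Bonferroni
adjusted for the number of chromosomes and reported on the ratio scale.

The module follows the statsmodels convention of a model object
(:class:`ChromosomeDosageModel`) whose ``fit`` returns a results object
(:class:`ChromosomeDosageResults`) with estimates, intervals, diagnostics
and a ``summary()`` table; :func:`chromosome_mf_regression` is the
one-call functional wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, DegenerateDesignError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ChromosomeDosageModel",
    "ChromosomeDosageResults",
    "chromosome_mf_regression",
    "mean_ratio_ci",
    "za_ratio",
    "density_log2mf",
    "classify_sex_bias",
    "classify_sex_bias_series",
    "bias_expression_anova",
    "positional_mf_profile",
]


class ChromosomeDosageModel:
    """No-intercept regression of per-gene log2(m:f) on chromosome identity.

    Parameters
    ----------
    mf_table : DataFrame
        Per-gene table with ``chromosome`` and ``log2_mf`` columns (the
        GC-adjusted column when correction has been applied).
    min_genes : int
        Chromosomes with fewer genes are excluded with a warning; at least
        two genes are needed for a within-chromosome variance contribution.

    Notes
    -----
    With indicator coding and no intercept the OLS coefficients are exactly
    the per-chromosome means of log2(m:f), identical to a regression of
    per-chromosome mean responses weighted by gene count. Inference uses the
    per-gene residual variance pooled across chromosomes.
    """

    def __init__(self, mf_table: pd.DataFrame, min_genes: int = 2):
        for col in ("chromosome", "log2_mf"):
            if col not in mf_table.columns:
                raise InputError(f"m:f table is missing column {col!r}")
        df = mf_table.loc[np.isfinite(mf_table["log2_mf"])].copy()
        counts = df["chromosome"].value_counts()
        small = counts.index[counts < min_genes]
        if len(small):
            logger.warning(
                "excluding chromosomes with < %d genes: %s", min_genes, sorted(small)
            )
            df = df.loc[~df["chromosome"].isin(small)]
        counts = df["chromosome"].value_counts()
        if len(counts) < 2:
            raise InputError("need at least 2 chromosomes with >= 2 genes each")
        self.data = df.reset_index(drop=True)
        self.chromosomes = sorted(counts.index)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ChromosomeDosageModel":
        return cls(df, **kwargs)

    def fit(self, alpha: float = 0.05) -> "ChromosomeDosageResults":
        """Fit the regression; CIs at joint level 1 - alpha (Bonferroni)."""
        design = pd.get_dummies(
            pd.Categorical(self.data["chromosome"], categories=self.chromosomes),
            dtype=float,
        )
        fit = sm.OLS(self.data["log2_mf"].to_numpy(), design.to_numpy()).fit()

        k = len(self.chromosomes)
        ci = fit.conf_int(alpha=alpha / k)  # Bonferroni across chromosomes
        counts = self.data["chromosome"].value_counts()
        table = pd.DataFrame(
            {
                "chromosome": self.chromosomes,
                "n_genes": [int(counts[c]) for c in self.chromosomes],
                "mean_log2_mf": fit.params,
                "mf_ratio": 2.0**fit.params,
                "ci_low": 2.0 ** ci[:, 0],
                "ci_high": 2.0 ** ci[:, 1],
            }
        )
        table["deviates_from_zero"] = (table["ci_low"] > 1.0) | (table["ci_high"] < 1.0)
        return ChromosomeDosageResults(
            chrom_table=table,
            f_statistic=float(fit.fvalue),
            f_pvalue=float(fit.f_pvalue),
            df_num=int(fit.df_model),
            df_den=int(fit.df_resid),
            alpha=alpha,
            _ols=fit,
        )


@dataclass
class ChromosomeDosageResults:
    """Per-chromosome m:f estimates with Bonferroni CIs and the global F-test."""

    chrom_table: pd.DataFrame
    f_statistic: float
    f_pvalue: float
    df_num: int
    df_den: int
    alpha: float
    _ols: object = field(default=None, repr=False)

    def ratio(self, chromosome: str) -> float:
        row = self._row(chromosome)
        return float(row["mf_ratio"])

    def _row(self, chromosome: str) -> pd.Series:
        hit = self.chrom_table.loc[self.chrom_table["chromosome"] == str(chromosome)]
        if hit.empty:
            raise InputError(f"chromosome {chromosome!r} not in the fitted model")
        return hit.iloc[0]

    def summary(self) -> str:
        lines = [
            "Chromosome-wise male:female expression ratio (no-intercept regression on log2 m:f)",
            f"Global F({self.df_num}, {self.df_den}) = {self.f_statistic:.2f}, "
            f"p = {self.f_pvalue:.3g}  [H0: all chromosome means = 0]",
            f"CIs: ratio scale, Bonferroni-adjusted joint level {1 - self.alpha:.0%}",
            "",
            f"{'chrom':>6} {'n':>6} {'m:f':>7} {'ci_low':>7} {'ci_high':>8}  deviates",
        ]
        for _, r in self.chrom_table.iterrows():
            flag = "*" if r["deviates_from_zero"] else ""
            lines.append(
                f"{r['chromosome']:>6} {r['n_genes']:>6d} {r['mf_ratio']:>7.3f} "
                f"{r['ci_low']:>7.3f} {r['ci_high']:>8.3f}  {flag}"
            )
        return "\n".join(lines)


def chromosome_mf_regression(mf_table: pd.DataFrame, alpha: float = 0.05) -> ChromosomeDosageResults:
    """One-call wrapper: build the model from an m:f table and fit it."""
    return ChromosomeDosageModel(mf_table).fit(alpha=alpha)


# ---------------------------------------------------------------------------
# bootstrap ratio intervals


def mean_ratio_ci(
    values,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed=None,
    mode: str = "ratio_of_means",
):
    """Nonparametric bootstrap percentile CI for a mean expression ratio.

    ``values`` is either a 1-D array of per-gene ratios
    (``mode="mean_of_ratios"`` averages them as they are;
    ``mode="geometric"`` averages on the log2 scale and exponentiates,
    matching a log2-transformed workflow) or an (n, 2) array of per-gene
    (male mean, female mean) pairs (``mode="ratio_of_means"``, the default —
    less biased at small n because no per-gene division is involved).
    Resampling is over genes.
    """
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)

    if mode == "geometric":
        if values.ndim != 1 or (values <= 0).any():
            raise InputError("geometric mode expects a 1-D array of positive ratios")
        values = np.log2(values)
        mode = "mean_of_ratios"
        back = lambda x: 2.0**x  # noqa: E731
    else:
        back = lambda x: x  # noqa: E731

    if mode == "ratio_of_means":
        if values.ndim != 2 or values.shape[1] != 2:
            raise InputError("ratio_of_means mode expects an (n, 2) array of sex means")
        n = len(values)
        if n < 2:
            raise InputError("need at least 2 genes")
        point = values[:, 0].mean() / values[:, 1].mean()
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = values[idx, 0].mean(axis=1) / values[idx, 1].mean(axis=1)
    elif mode == "mean_of_ratios":
        if values.ndim != 1:
            raise InputError("mean_of_ratios mode expects a 1-D array of ratios")
        n = len(values)
        if n < 2:
            raise InputError("need at least 2 genes")
        point = values.mean()
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = values[idx].mean(axis=1)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    lo, hi = np.quantile(boot, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(back(point)), float(back(lo)), float(back(hi))


def za_ratio(
    expr,
    chromosomes: pd.Series,
    sex: str,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed=None,
):
    """Z:A ratio for one sex on the log2 scale (ratio of geometric means).

    Per-gene expression is the within-sex mean, log2-transformed; the Z:A
    ratio is ``2**(mean log2 Z - mean log2 autosomes)``, with a gene-level
    bootstrap of the two sets independently. Working on log2 keeps the
    estimate from being dominated by a handful of highly expressed genes.
    Genes with a zero within-sex mean are excluded. A value below 1 in
    females together with ~1 in males indicates an only partly compensated
    single-dose Z.
    """
    sample_ids = expr.sample_ids(sex)
    if not sample_ids:
        raise InputError(f"no samples of sex {sex!r}")
    per_gene = expr.values[sample_ids].mean(axis=1)
    chromosomes = chromosomes.reindex(per_gene.index)
    expressed = per_gene > 0
    z_vals = np.log2(per_gene[(chromosomes == "Z") & expressed].to_numpy(dtype=float))
    a_vals = np.log2(
        per_gene[(chromosomes != "Z") & chromosomes.notna() & expressed].to_numpy(dtype=float)
    )
    if len(z_vals) == 0:
        raise InputError("no Z-linked genes present")
    if len(a_vals) == 0:
        raise InputError("no autosomal genes present")

    point = z_vals.mean() - a_vals.mean()
    rng = np.random.default_rng(seed)
    zi = rng.integers(0, len(z_vals), size=(n_boot, len(z_vals)))
    ai = rng.integers(0, len(a_vals), size=(n_boot, len(a_vals)))
    boot = z_vals[zi].mean(axis=1) - a_vals[ai].mean(axis=1)
    lo, hi = np.quantile(boot, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(2.0**point), float(2.0**lo), float(2.0**hi)


# ---------------------------------------------------------------------------
# density of log2(m:f)


def density_log2mf(values, n_grid: int = 512, pad_bandwidths: float = 3.0):
    """Gaussian kernel density of log2(m:f) with Silverman's bandwidth.

    Returns ``(grid, density)``; the density integrates to 1 on the grid to
    trapezoid accuracy. A bimodal curve with modes near 0 and 1 is the
    signature of a gene set mixing compensated and uncompensated Z genes.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise InputError("need at least 2 finite values")
    if np.ptp(values) == 0.0:
        raise DegenerateDesignError("all values identical; kernel bandwidth is zero")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - pad_bandwidths * bw, values.max() + pad_bandwidths * bw, n_grid)
    return grid, kde(grid)


# ---------------------------------------------------------------------------
# sex-bias classes


MALE_BIAS_MIN = 2.0
UNBIASED_RANGE = (0.8, 1.2)
FEMALE_BIAS_MAX = 0.5


def classify_sex_bias(mf_ratio: float) -> str:
    """Assign a sex-bias class to an m:f ratio.

    ``> 2`` male_biased, ``(0.8, 1.2)`` unbiased, ``< 0.5`` female_biased.
    The gaps [0.5, 0.8] and [1.2, 2] are deliberate: genes there are
    ``unclassified`` rather than forced into a class.
    """
    ratio = float(mf_ratio)
    if not ratio > 0:
        raise InputError(f"m:f ratio must be positive, got {ratio}")
    if ratio > MALE_BIAS_MIN:
        return "male_biased"
    if UNBIASED_RANGE[0] < ratio < UNBIASED_RANGE[1]:
        return "unbiased"
    if ratio < FEMALE_BIAS_MAX:
        return "female_biased"
    return "unclassified"


def classify_sex_bias_series(mf_ratio: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_sex_bias` over a Series of ratios."""
    return mf_ratio.map(classify_sex_bias)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    r_squared: float
    class_means: dict
    class_sizes: dict
    posthoc: dict  # (class_a, class_b) -> Bonferroni-adjusted two-sided p


def bias_expression_anova(expr_level, classes) -> AnovaResult:
    """One-way ANOVA of expression level on sex-bias class, with post hoc tests.

    ``expr_level`` is per-gene log2 expression in one sex; ``classes`` the
    matching bias labels. Unclassified genes are excluded. Post hoc pairwise
    two-sample t tests are Bonferroni adjusted for the number of pairs.
    """
    level = np.asarray(expr_level, dtype=float)
    cls = pd.Series(list(classes))
    if len(level) != len(cls):
        raise InputError("expr_level and classes must have the same length")
    keep = cls.isin(["male_biased", "unbiased", "female_biased"]).to_numpy()
    level, cls = level[keep], cls[keep].reset_index(drop=True)
    groups = {c: level[(cls == c).to_numpy()] for c in cls.unique()}
    groups = {c: v for c, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise InputError("need at least 2 non-empty bias classes")

    k, n = len(groups), len(level)
    grand = level.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_total = ((level - grand) ** 2).sum()
    df1, df2 = k - 1, n - k
    ss_within = ss_total - ss_between
    if ss_total == 0.0:
        f_stat, p, r2 = 0.0, 1.0, 0.0
    elif ss_within <= 0.0:
        f_stat, p, r2 = float("inf"), 0.0, 1.0
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
        r2 = ss_between / ss_total

    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    posthoc = {}
    for a, b in pairs:
        t_res = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        posthoc[(a, b)] = float(min(1.0, t_res.pvalue * len(pairs)))

    return AnovaResult(
        f_statistic=float(f_stat),
        df_num=df1,
        df_den=df2,
        p_value=float(p),
        r_squared=float(r2),
        class_means={c: float(v.mean()) for c, v in groups.items()},
        class_sizes={c: int(len(v)) for c, v in groups.items()},
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# positional profile


def positional_mf_profile(
    mf_table: pd.DataFrame,
    chromosome: str = "Z",
    window_genes: int = 10,
    value_col: str | None = None,
) -> pd.DataFrame:
    """Sliding-window mean of log2(m:f) along a chromosome.

    Genes on the requested chromosome are ordered by ``position_bp`` (1-based)
    and averaged over windows of ``window_genes`` consecutive genes, step 1.
    The reported position is the window's central gene. Uses the GC-adjusted
    column when present unless ``value_col`` overrides.
    """
    df = mf_table.loc[mf_table["chromosome"] == str(chromosome)].copy()
    if value_col is None:
        value_col = "log2_mf_gc_adjusted" if "log2_mf_gc_adjusted" in df.columns else "log2_mf"
    if "position_bp" not in df.columns:
        raise InputError("m:f table has no position_bp column")
    if df["position_bp"].isna().any():
        raise InputError(f"missing positions for chromosome {chromosome!r}")
    if len(df) < window_genes:
        raise InputError(
            f"chromosome {chromosome!r} has {len(df)} genes, fewer than window_genes={window_genes}"
        )
    df = df.sort_values("position_bp").reset_index(drop=True)
    rolled = df[value_col].rolling(window_genes).mean().dropna().to_numpy()
    center = window_genes // 2
    positions = df["position_bp"].to_numpy()[center : center + len(rolled)]
    return pd.DataFrame({"position_bp": positions, "mean_log2_mf": rolled})
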
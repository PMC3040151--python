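"""Cross-species comparison of sex-biased expression.

If the degree of dosage compensation of individual Z-linked genes is
conserved, their m:f ratios should correlate across species once the genes
are matched through 1:1(:1) orthology in a common identifier namespace.
The steps are: collapse probe-level ratios to one value per gene (microarray
platforms often carry several probes per gene), inner-join the per-species
tables on gene id (optionally restricted to the Z or to autosomes), and
compute pairwise Pearson correlations of log2 m:f.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

SPECIES_MF_COLUMNS = ["species", "gene_id", "mf_ratio", "chromosome"]


def collapse_probe_ids(probe_mf: pd.DataFrame, probe_to_gene: dict | pd.Series) -> pd.DataFrame:
    """Average probe-level m:f ratios to one value per gene.

    ``probe_mf`` needs columns ``probe_id`` and ``mf_ratio``. Every probe must
    map to at most one gene; unmapped probes are dropped.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.index.duplicated().any():
        dup = mapping.index[mapping.index.duplicated()][0]
        raise InputError(f"probe {dup!r} maps to multiple genes")
    df = probe_mf.copy()
    df["gene_id"] = df["probe_id"].map(mapping)
    df = df.dropna(subset=["gene_id"])
    out = df.groupby("gene_id", as_index=False)["mf_ratio"].mean()
    return out


def intersect_orthologues(tables: list[pd.DataFrame], subset: str = "all") -> pd.DataFrame:
    """Align 2–3 per-species m:f tables on shared gene ids.

    Each table needs columns ``species``, ``gene_id``, ``mf_ratio`` and
    ``chromosome``. ``subset`` restricts to ``"Z"`` or ``"autosomes"``
    (chromosome label judged in the first table's namespace). Returns a
    genes x species matrix of m:f ratios sorted by gene id.
    """
    if not 2 <= len(tables) <= 3:
        raise InputError(f"expected 2 or 3 species tables, got {len(tables)}")
    aligned = None
    chrom = None
    for tab in tables:
        missing = [c for c in SPECIES_MF_COLUMNS if c not in tab.columns]
        if missing:
            raise InputError(f"species table is missing columns {missing}")
        species = tab["species"].iloc[0]
        if tab["gene_id"].duplicated().any():
            raise InputError(f"duplicate gene ids in table for {species!r}")
        col = tab.set_index("gene_id")["mf_ratio"].rename(species)
        if aligned is None:
            aligned = col.to_frame()
            chrom = tab.set_index("gene_id")["chromosome"].astype(str)
        else:
            aligned = aligned.join(col, how="inner")
    if subset == "Z":
        aligned = aligned.loc[chrom.reindex(aligned.index) == "Z"]
    elif subset == "autosomes":
        aligned = aligned.loc[chrom.reindex(aligned.index) != "Z"]
    elif subset != "all":
        raise InputError(f"unknown subset {subset!r}")
    if aligned.empty:
        logger.warning("empty orthologue intersection (subset=%s)", subset)
    return aligned.sort_index()


def correlate_mf(aligned: pd.DataFrame, log_scale: bool = True, method: str = "pearson"):
    """Pairwise correlation of per-species m:f vectors.

    Returns three species x species DataFrames ``(r, p, n)``. Pairs with
    fewer than 3 complete observations are set to missing. ``log_scale``
    correlates log2 ratios (default), which also makes r invariant to
    per-species multiplicative rescaling.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"method must be pearson or spearman, got {method!r}")
    data = np.log2(aligned) if log_scale else aligned
    species = list(data.columns)
    r = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    p = pd.DataFrame(np.nan, index=species, columns=species)
    n = pd.DataFrame(0, index=species, columns=species, dtype=int)
    for sp in species:
        n.loc[sp, sp] = int(data[sp].notna().sum())
    for a, b in combinations(species, 2):
        pair = data[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < 3:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        if method == "pearson":
            res = stats.pearsonr(pair[a], pair[b])
        else:
            res = stats.spearmanr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p, n


def correlation_long_table(r: pd.DataFrame, p: pd.DataFrame, n: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Flatten the correlation matrices into the output row format."""
    rows = []
    for a, b in combinations(list(r.columns), 2):
        rows.append(
            {"pair": f"{a}-{b}", "subset": subset, "n": int(n.loc[a, b]),
             "r": float(r.loc[a, b]), "p": float(p.loc[a, b])}
        )
    return pd.DataFrame(rows)
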
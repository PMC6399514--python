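"""Pearson association of promoter methylation with expression and phenotype.

Correlations are computed on per-group (per-week) aggregates — the overall
integral methylation rate, per-site rates, mean relative expression, mean
eggshell color — mirroring how clone-based methylation studies pair their
small weekly series.  Significance uses the exact t transform of r with
n-2 degrees of freedom; per-site tables optionally carry a
Benjamini-Hochberg adjusted column.

A "key" regulatory CpG site is one that is both significantly negatively
correlated with expression and located inside a predicted transcription
factor binding site: methylation there plausibly blocks factor binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "pearson",
    "site_correlation_table",
    "flag_key_sites",
    "significance_stars",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    adjusted_p: float | None = None


def significance_stars(p: float) -> str:
    """Annotation convention: ** for p < 0.01, * for p < 0.05, blank otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson(x, y, labels: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with two-sided t-based p-value.

    Pairs with a missing member are dropped (and counted) first; n >= 3
    complete pairs and non-zero variance in both series are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete pair(s)", stacklevel=2)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    for series, name in ((x, labels[0]), (y, labels[1])):
        if np.ptp(series) == 0:
            raise ValueError(f"series {name!r} has zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def site_correlation_table(
    site_rates: pd.DataFrame,
    phenotype: pd.Series,
    adjust: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each CpG site's per-group rate series with a phenotype series.

    ``site_rates``: groups (index) x site ordinals (columns); ``phenotype``
    indexed by the same groups.  A site with undefined rates in more than
    half the groups is excluded with a warning.  ``adjust`` is 'none'
    (per-site raw p, the convention of small BSP studies) or 'bh'
    (Benjamini-Hochberg).
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    common = site_rates.index.intersection(phenotype.index)
    rates = site_rates.loc[common]
    pheno = phenotype.loc[common].astype(float)
    rows = []
    for site in rates.columns:
        series = rates[site].astype(float)
        if series.isna().sum() > len(series) // 2:
            warnings.warn(
                f"site {site}: rate undefined in most groups; excluded",
                stacklevel=2,
            )
            continue
        res = pearson(series.to_numpy(), pheno.to_numpy(),
                      labels=(f"site_{site}", phenotype.name or "phenotype"))
        rows.append({"site": site, "r": res.r, "p": res.p, "n": res.n})
    table = pd.DataFrame(rows).set_index("site").sort_index()
    if adjust == "bh":
        table["adjusted_p"] = multipletests(table["p"], method="fdr_bh")[1]
    table["stars"] = [
        significance_stars(p)
        for p in (table["adjusted_p"] if adjust == "bh" else table["p"])
    ]
    return table


def flag_key_sites(
    correlations: pd.DataFrame,
    tfbs_covered: set[int] | list[int],
    alpha: float = 0.05,
) -> list[int]:
    """Sites both significantly negatively correlated with expression at
    ``alpha`` and covered by a predicted TF binding site."""
    covered = set(tfbs_covered)
    p_col = "adjusted_p" if "adjusted_p" in correlations.columns else "p"
    flagged = [
        int(site)
        for site, row in correlations.iterrows()
        if row["r"] < 0 and row[p_col] < alpha and int(site) in covered
    ]
    return sorted(flagged)
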
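"""Descriptive statistics of the mapping population's phenotypes.

Colorimeter readings (L = luminosity, a = green-red, b = blue-yellow) come
as per-plant means of three replicate measurements; a replicate-level file
can be averaged first. The summary reports ranges, standard deviations,
pairwise Pearson correlations with two-sided p-values, and a Shapiro-Wilk
normality test per index — a bimodal, non-normal distribution in an F2 is
the classic signature of one or a few major QTLs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PhenoSummary:
    stats: pd.DataFrame        # index = trait; min, max, mean, sd
    corr: pd.DataFrame         # Pearson r, unit diagonal
    corr_p: pd.DataFrame       # two-sided p-values (NaN on diagonal)
    normality: pd.DataFrame    # Shapiro-Wilk W and p per trait
    constant_traits: list[str]

    def summary(self) -> str:
        lines = ["Phenotype summary", self.stats.round(3).to_string(), "",
                 "Pearson correlations", self.corr.round(3).to_string(), "",
                 "Shapiro-Wilk normality",
                 self.normality.round(4).to_string()]
        if self.constant_traits:
            lines.append(f"Constant traits (correlation undefined): "
                         f"{', '.join(self.constant_traits)}")
        return "\n".join(lines)


def average_replicates(pheno: pd.DataFrame,
                       individual_col: str = "individual") -> pd.DataFrame:
    """Collapse a replicate-level table to per-individual means."""
    return pheno.groupby(individual_col).mean(numeric_only=True)


def summarize_phenotypes(pheno: pd.DataFrame) -> PhenoSummary:
    """Descriptive statistics, correlations and normality tests.

    Constant columns are flagged (their correlations are NaN), not raised.
    Requires at least 3 individuals.
    """
    if len(pheno) < 3:
        raise ValueError("need at least 3 individuals")
    traits = list(pheno.columns)
    desc = pd.DataFrame({
        "min": pheno.min(), "max": pheno.max(),
        "mean": pheno.mean(), "sd": pheno.std(ddof=1)})
    constant = [t for t in traits if pheno[t].std(ddof=1) == 0]
    corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    corr_p = pd.DataFrame(np.full((len(traits), len(traits)), np.nan),
                          index=traits, columns=traits)
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            if t1 in constant or t2 in constant:
                corr.loc[t1, t2] = corr.loc[t2, t1] = np.nan
                continue
            r, p = stats.pearsonr(pheno[t1], pheno[t2])
            corr.loc[t1, t2] = corr.loc[t2, t1] = r
            corr_p.loc[t1, t2] = corr_p.loc[t2, t1] = p
    rows = []
    for t in traits:
        if t in constant:
            rows.append({"W": np.nan, "p": np.nan})
        else:
            w, p = stats.shapiro(pheno[t])
            rows.append({"W": w, "p": p})
    normality = pd.DataFrame(rows, index=traits)
    return PhenoSummary(desc, corr, corr_p, normality, constant)


def write_summary(summary: PhenoSummary, stats_path, corr_path) -> None:
    summary.stats.to_csv(stats_path, sep="\t")
    summary.corr.to_csv(corr_path)
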
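"""Validation statistics: automated-vs-manual agreement and heritability.

Two questions follow every phenotyping pipeline: does it agree with manual
measurements (squared Pearson correlation of automated vs manual values),
and are the trait values repeatable across replicates of a genotype
(broad-sense heritability).  Heritability is estimated by method-of-moments
one-way random-effects ANOVA: genotype is the random effect, replicates the
residual, and

    sigma2_G = (MS_genotype - MS_error) / r_h      (clipped at 0)
    H2_mean  = sigma2_G / (sigma2_G + sigma2_e / r_h)   (entry-mean basis)
    H2_plot  = sigma2_G / (sigma2_G + sigma2_e)         (single-plot basis)

where r_h is the harmonic mean of per-genotype replicate counts (equal to
the plain mean for balanced designs).  The entry-mean basis is the headline
number: it answers how repeatable the genotype means are at the observed
replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def r_squared(auto, manual) -> tuple[float, float]:
    """Squared Pearson correlation between automated and manual values,
    with the two-sided p-value of the correlation test."""
    a = np.asarray(auto, float)
    m = np.asarray(manual, float)
    if a.shape != m.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(m) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(a, m)
    return float(res.statistic ** 2), float(res.pvalue)


@dataclass
class HeritabilityResult:
    trait: str
    h2_mean: float          # entry-mean basis (headline)
    h2_plot: float          # single-plot basis
    sigma2_g: float
    sigma2_e: float
    n_genotypes: int
    r_harmonic: float
    clipped: bool           # negative genetic variance clipped to 0

    def as_dict(self) -> dict:
        return {"trait": self.trait, "H2_mean": self.h2_mean,
                "H2_plot": self.h2_plot, "sigma2_G": self.sigma2_g,
                "sigma2_e": self.sigma2_e, "n_genotypes": self.n_genotypes,
                "r_harmonic": self.r_harmonic, "clipped": self.clipped}


def heritability(table: pd.DataFrame, trait: str, genotype_col: str = "genotype",
                 value_col: str = "value", trait_col: str = "trait"
                 ) -> HeritabilityResult:
    """Broad-sense heritability of one trait from a (genotype, replicate,
    trait, value) table; see module docstring for the estimator."""
    df = table
    if trait_col in df.columns:
        df = df[df[trait_col] == trait]
    df = df.dropna(subset=[value_col])
    groups = [g[value_col].to_numpy(float) for _, g in df.groupby(genotype_col)]
    groups = [g for g in groups if len(g) >= 1]
    k = len(groups)
    if k < 2:
        raise ValueError("heritability needs >= 2 genotypes")
    counts = np.array([len(g) for g in groups], float)
    if not (counts >= 2).any():
        raise ValueError("heritability needs >= 2 replicates for some genotype")
    n_total = counts.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_g = ss_between / (k - 1)
    dfe = n_total - k
    ms_e = ss_within / dfe if dfe > 0 else 0.0
    r_h = float(len(counts) / (1.0 / counts).sum())
    sigma2_g = (ms_g - ms_e) / r_h
    clipped = sigma2_g < 0
    sigma2_g = max(0.0, sigma2_g)
    denom_mean = sigma2_g + ms_e / r_h
    denom_plot = sigma2_g + ms_e
    h2_mean = sigma2_g / denom_mean if denom_mean > 0 else 0.0
    h2_plot = sigma2_g / denom_plot if denom_plot > 0 else 0.0
    return HeritabilityResult(trait=trait, h2_mean=float(np.clip(h2_mean, 0, 1)),
                              h2_plot=float(np.clip(h2_plot, 0, 1)),
                              sigma2_g=float(sigma2_g), sigma2_e=float(ms_e),
                              n_genotypes=k, r_harmonic=r_h, clipped=clipped)


def heritability_table(table: pd.DataFrame, trait_col: str = "trait",
                       **kwargs) -> pd.DataFrame:
    """Heritability of every trait in a long-format table, as a DataFrame."""
    rows = []
    for trait in sorted(table[trait_col].unique()):
        try:
            rows.append(heritability(table, trait, trait_col=trait_col,
                                     **kwargs).as_dict())
        except ValueError as exc:
            rows.append({"trait": trait, "H2_mean": np.nan, "H2_plot": np.nan,
                         "sigma2_G": np.nan, "sigma2_e": np.nan,
                         "n_genotypes": np.nan, "r_harmonic": np.nan,
                         "clipped": False, "error": str(exc)})
    return pd.DataFrame(rows)
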
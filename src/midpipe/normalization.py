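"""Between-isotopologue and between-sample normalization.

Two stages put corrected intensities on comparable scales:

1. *Between isotopologues*: every isotopologue of a metabolite is divided
   by the metabolite's mean abundance — the across-sample mean of its
   per-sample isotopologue sums — so each metabolite has mean abundance 1
   regardless of ionization efficiency.
2. *Between samples*: per-sample size factors are weighted means of the
   (normalized) analyte signals, each analyte weighted by the inverse of
   its relative variance (squared CV across samples), so stable analytes
   dominate the estimate.  Factors are anchored to geometric mean 1.

MIDs are per-sample fractions and therefore invariant to size factors;
size factors matter for abundance comparisons only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import IsotopologueTable

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class SizeFactors:
    """Per-sample scaling constants and the analyte weights behind them.

    ``factors`` has geometric mean 1 over samples; ``weights`` and
    ``relative_variance`` are indexed by the (metabolite, shift) rows that
    entered the weighting set.
    """

    factors: pd.Series
    weights: pd.Series
    relative_variance: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise NormalizationError("size factors must be positive")
        gm = np.exp(np.log(self.factors).mean())
        if abs(gm - 1.0) > 1e-9:
            raise NormalizationError(f"size factors not anchored to geometric mean 1 ({gm})")


def normalize_between_isotopologues(
    corrected: IsotopologueTable,
) -> tuple[IsotopologueTable, list[str]]:
    """Divide each metabolite's values by its mean abundance across samples.

    The mean abundance A_m is the across-sample mean of per-sample
    isotopologue sums (samples whose vector is wholly missing are skipped).
    Metabolites with A_m = 0 are left untouched and returned as flagged.
    Afterwards every scaled metabolite has across-sample mean abundance 1.
    """
    values = corrected.values.copy()
    flagged: list[str] = []
    mets = values.index.get_level_values("metabolite")
    for met in corrected.metabolites:
        mask = mets == met
        block = values.loc[mask]
        sums = block.sum(axis=0, skipna=False)  # NaN where vector missing
        mean_abundance = sums.mean(skipna=True)
        if not np.isfinite(mean_abundance) or mean_abundance == 0:
            flagged.append(met)
            continue
        values.loc[mask] = block.to_numpy() / mean_abundance
    if flagged:
        logger.warning("mean abundance is 0 or undefined for %s; left unscaled", flagged)
    return corrected.advance(values, corrected.stage), flagged


def compute_size_factors(
    table: IsotopologueTable,
    sample_ids=None,
    weight_clamp_quantile: float = 0.99,
) -> SizeFactors:
    """Inverse-relative-variance-weighted per-sample size factors.

    Analytes with any missing value across the chosen samples are excluded
    from the weighting set.  The relative variance of analyte k is
    var_k/mean_k² (squared CV across samples); its weight is the inverse,
    clamped at the ``weight_clamp_quantile`` quantile of finite weights so
    zero-variance analytes cannot dictate the factors.  If no analyte has
    a finite weight (e.g. all samples identical) equal weights are used.
    The raw weighted sums are anchored to geometric mean 1.
    """
    sub = table.values if sample_ids is None else table.values[list(sample_ids)]
    if sub.shape[1] < 2:
        raise NormalizationError("size factors need at least 2 samples")
    complete = sub.dropna(axis=0)
    means = complete.mean(axis=1)
    informative = complete.loc[means > 0]
    if informative.empty:
        raise NormalizationError("no complete analytes with signal; cannot weight")
    means = informative.mean(axis=1)
    var = informative.var(axis=1, ddof=1)
    rel_var = var / means**2
    with np.errstate(divide="ignore"):
        weights = 1.0 / rel_var
    finite = weights[np.isfinite(weights)]
    if finite.empty:
        logger.warning("all analytes zero-variance; using equal weights")
        weights = pd.Series(1.0, index=weights.index)
    else:
        cap = finite.quantile(weight_clamp_quantile)
        weights = weights.clip(upper=cap)
    raw = (informative.mul(weights, axis=0)).sum(axis=0) / weights.sum()
    if (raw <= 0).any():
        raise NormalizationError("non-positive weighted sum for some sample")
    factors = raw / np.exp(np.log(raw).mean())
    return SizeFactors(factors=factors, weights=weights, relative_variance=rel_var)


def apply_size_factors(table: IsotopologueTable, sf: SizeFactors) -> IsotopologueTable:
    """Divide each covered sample column by its size factor; stage becomes normalized.

    Columns without a factor (e.g. blank samples) raise unless they are
    absent from ``sf.factors``' index on purpose — every biological sample
    must be covered.
    """
    values = table.values.copy()
    missing = [s for s in values.columns if s not in sf.factors.index]
    if missing:
        raise NormalizationError(f"no size factor for samples: {missing}")
    values = values.div(sf.factors[values.columns], axis=1)
    return table.advance(values, "normalized")


def write_size_factors(sf: SizeFactors, path) -> None:
    sf.factors.rename("size_factor").to_csv(path, sep="\t", index_label="sample")
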
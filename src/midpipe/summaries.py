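"""Derived quantities: abundances, MIDs, fractional labeling, diagnostic ratios.

A metabolite's abundance in a sample is the sum of its isotopologue
intensities; its mass isotopomer distribution (MID) is the vector of
isotopologue fractions relative to that sum.  Fractional labeling
compresses a MID into the mean fraction of labeled carbon atoms,
F = Σ_k k·π_k / n — the quantity usually rendered as color intensity on
pathway flux maps.  Isotopologue ratios such as m+3/m+2 in TCA-cycle
intermediates contrast anaplerotic (pyruvate carboxylase, m+3) against
oxidative (PDH/acetyl-CoA, m+2) entry of glucose carbon.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import IsotopologueTable, MoleculeSpec, SampleMeta


def metabolite_abundance(norm: IsotopologueTable) -> pd.DataFrame:
    """Sum of non-missing isotopologue abundances per (metabolite, sample).

    Isotopologues removed by group cleaning (missing) are skipped — their
    true contribution is near the limit of detection by construction.
    The abundance itself is missing only when the metabolite's whole
    vector is missing in that sample.
    """
    return norm.values.groupby(level="metabolite", sort=True).sum(min_count=1)


def compute_mid(norm: IsotopologueTable) -> pd.DataFrame:
    """Isotopologue fractions relative to per-sample isotopologue sums.

    Returns a table shaped like the input.  Sums run over the non-missing
    isotopologues of the vector; a fraction is undefined (NaN) where the
    isotopologue itself is missing or where the sum is zero or missing.
    """
    sums = norm.values.groupby(level="metabolite", sort=False).transform(
        lambda b: b.sum(min_count=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mid = norm.values / sums.where(sums != 0)
    return mid


def fractional_labeling(
    mid: pd.DataFrame, molecules: Mapping[str, MoleculeSpec]
) -> pd.DataFrame:
    """Mean fraction of labeled carbons per metabolite-sample: Σ k·π_k / n.

    Missing MID components (cleaned near-LOD isotopologues) are skipped;
    the result is undefined (NaN) for metabolites with zero carbons or a
    wholly missing MID.
    """
    shifts = mid.index.get_level_values("shift").to_numpy()
    weighted = mid.mul(shifts, axis=0)
    total = weighted.groupby(level="metabolite", sort=True).sum(min_count=1)
    n = pd.Series({m: molecules[m].n_carbons for m in total.index}, name="n")
    return total.div(n.where(n > 0), axis=0)


def isotopologue_ratio(
    mid: pd.DataFrame,
    metabolites: Iterable[str],
    k_num: int,
    k_den: int,
) -> pd.DataFrame:
    """Per metabolite-sample ratio π_{k_num} / π_{k_den}.

    Missing where the denominator fraction is zero or either fraction is
    undefined.  Rows are metabolites, columns samples.
    """
    mets = list(metabolites)
    num = mid.xs(k_num, level="shift").reindex(mets)
    den = mid.xs(k_den, level="shift").reindex(mets)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den.where(den != 0)
    return r


def group_mean_ratio(ratios: pd.DataFrame, meta: SampleMeta) -> pd.Series:
    """Arithmetic mean of per-sample, per-metabolite ratios within each group."""
    groups = meta.groups()
    cols = [c for c in ratios.columns if c in groups.index]
    long = ratios[cols].stack(future_stack=True)
    by = long.index.get_level_values(-1).map(groups)
    return long.groupby(by).mean()


def metabolite_ratio(
    abundance: pd.DataFrame, num: str, den: str, log2: bool = False
) -> pd.Series:
    """Per-sample abundance ratio of two metabolites (e.g. fumarate/succinate).

    Missing propagates; zero denominators yield missing.  Both members
    share each sample's size factor, so normalized-scale ratios equal
    raw-scale ratios.
    """
    for m in (num, den):
        if m not in abundance.index:
            raise KeyError(f"metabolite {m!r} not in abundance table")
    d = abundance.loc[den]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = abundance.loc[num] / d.where(d != 0)
    if log2:
        r = np.log2(r.where(r > 0))
    return r.rename(f"{num}/{den}")
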
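"""Blank-based quantification thresholds and missingness filters.

A signal is quantifiable when it clearly exceeds the background seen in
blank injections.  For each batch, the quantification threshold of every
isotopologue is the blank mean plus two blank standard deviations.
Intensities below the blank mean are zeroed; intensities between the
blank mean and the threshold are linearly mapped onto [0, T] so the
corrected scale is continuous at T and monotone.  Downstream testing only
uses analytes with at least two biological replicates above threshold,
and sample groups in which more than one third of the values fall below
threshold are removed entirely (set to missing).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .data_model import IsotopologueTable, SampleMeta, ThresholdSet

logger = logging.getLogger(__name__)


class QuantificationError(ValueError):
    pass


def compute_blank_thresholds(raw: IsotopologueTable, meta: SampleMeta) -> ThresholdSet:
    """Per-batch blank statistics: mean, sample SD, and T = mean + 2*SD.

    Requires at least two blank samples per batch (the SD is undefined
    otherwise); rows whose blank values are all missing in a batch get a
    permissive mean 0 / threshold 0 with a warning.
    """
    blanks = meta.df[meta.df["is_blank"]]
    if blanks.empty:
        raise QuantificationError("no blank samples in metadata")
    batches = list(dict.fromkeys(meta.df["batch"]))
    frames = []
    for batch in batches:
        ids = blanks.index[blanks["batch"] == batch]
        ids = [s for s in ids if s in raw.values.columns]
        if len(ids) == 0:
            raise QuantificationError(f"batch {batch!r} has no blank samples")
        if len(ids) < 2:
            raise QuantificationError(
                f"batch {batch!r} has {len(ids)} blank sample(s); >=2 required"
            )
        vals = raw.values[ids]
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        all_missing = vals.isna().all(axis=1)
        if all_missing.any():
            logger.warning(
                "batch %r: %d analyte(s) absent from blanks; threshold set to 0",
                batch,
                int(all_missing.sum()),
            )
            mu = mu.where(~all_missing, 0.0)
            sd = sd.where(~all_missing, 0.0)
        df = pd.DataFrame(
            {"blank_mean": mu, "blank_sd": sd, "threshold": mu + 2.0 * sd}
        )
        df["batch"] = batch
        frames.append(df.set_index("batch", append=True))
    out = pd.concat(frames).sort_index()
    return ThresholdSet(out)


def _map_column(x: np.ndarray, mu: np.ndarray, thr: np.ndarray) -> np.ndarray:
    """Piecewise-linear threshold map for one sample column.

    x < mu -> 0; mu <= x < T -> T*(x-mu)/(T-mu); x >= T -> x.
    Degenerate T == mu: zero below T, pass-through at or above.
    """
    out = x.copy()
    below = x < mu
    out[below] = 0.0
    span = thr - mu
    mid = (~below) & (x < thr) & (span > 0)
    out[mid] = thr[mid] * (x[mid] - mu[mid]) / span[mid]
    return out


def apply_threshold_correction(
    raw: IsotopologueTable, thr: ThresholdSet, meta: SampleMeta
) -> IsotopologueTable:
    """Zero sub-blank intensities and linearly rescale the blank-to-threshold band.

    Each sample column uses the thresholds of its own batch.  The map is
    continuous at T and monotone; values at or above T pass through
    unchanged.  Output stage is ``thresholded``.  The thresholds are
    defined on the raw intensity scale, so a table that is already
    thresholded is returned unchanged (the operation is idempotent at the
    stage level; re-mapping mapped values would corrupt them).
    """
    if raw.stage != "raw":
        return IsotopologueTable(values=raw.values.copy(), stage=raw.stage)
    values = raw.values.copy()
    for sample in values.columns:
        batch = meta.batch_of(sample)
        stats = thr.for_batch(batch).reindex(values.index)
        if stats["threshold"].isna().any():
            missing = stats.index[stats["threshold"].isna()].tolist()[:5]
            raise QuantificationError(
                f"thresholds missing for batch {batch!r}, e.g. rows {missing}"
            )
        values[sample] = _map_column(
            values[sample].to_numpy(dtype=float),
            stats["blank_mean"].to_numpy(dtype=float),
            stats["threshold"].to_numpy(dtype=float),
        )
    return raw.advance(values, "thresholded")


def _threshold_matrix(
    table: IsotopologueTable, thr: ThresholdSet, meta: SampleMeta, sample_ids
) -> pd.DataFrame:
    """Per-cell threshold T aligned to the table, per sample's batch."""
    cols = {}
    for sample in sample_ids:
        batch = meta.batch_of(sample)
        cols[sample] = thr.for_batch(batch)["threshold"].reindex(table.values.index)
    return pd.DataFrame(cols)


def flag_testable(
    thresholded: IsotopologueTable, thr: ThresholdSet, meta: SampleMeta
) -> pd.Series:
    """Mark analytes with at least two biological replicates above threshold.

    Returns a boolean Series over (metabolite, shift) rows; only testable
    analytes enter differential statistics.
    """
    bio = [s for s in thresholded.values.columns if s in set(meta.biological_ids)]
    tmat = _threshold_matrix(thresholded, thr, meta, bio)
    above = thresholded.values[bio] > tmat
    return above.sum(axis=1) >= 2


def clean_groups(
    thresholded: IsotopologueTable,
    thr: ThresholdSet,
    meta: SampleMeta,
    target: IsotopologueTable | None = None,
) -> IsotopologueTable:
    """Remove analyte values from groups dominated by sub-threshold signal.

    For each (analyte, group): if strictly more than 1/3 of the group's
    values lie below the quantification threshold, all of that group's
    values for the analyte are set to missing.  Missing values count as
    below threshold.  Blank samples are untouched.

    Sub-threshold membership is always judged on ``thresholded`` (the
    intensity scale the thresholds live on); the resulting mask is applied
    to ``target`` when given — typically the corrected/normalized table,
    mirroring the position of cleaning after normalization in the
    processing order — otherwise to ``thresholded`` itself.
    """
    if target is None:
        target = thresholded
    values = target.values.copy()
    groups = meta.groups()
    for group, members in groups.groupby(groups).groups.items():
        cols = [s for s in members if s in values.columns]
        if not cols:
            continue
        tmat = _threshold_matrix(thresholded, thr, meta, cols)
        sub = thresholded.values[cols]
        below = sub.isna() | (sub < tmat)
        n_below = below.sum(axis=1).to_numpy()
        # strict ">1/3" via exact integer comparison
        drop = n_below * 3 > len(cols)
        if drop.any():
            values.loc[drop, cols] = np.nan
    return replace(target, values=values)
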
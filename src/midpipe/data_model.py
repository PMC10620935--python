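"""Tabular containers and TSV/CSV readers/writers for isotopologue data.

The central object is the :class:`IsotopologueTable`: a non-negative real
matrix whose rows are keyed by ``(metabolite, shift)`` — the isotopologue
m+k of a metabolite — and whose columns are samples.  Tables carry a
``stage`` tag recording how far through the pipeline they have travelled;
stages only move forward (raw → thresholded → corrected → normalized).

On disk, row keys use the ``<metabolite>_m<k>`` dialect common to
peak-integration exports (``lac_m0``, ``lac_m1``, ...); the separator is
configurable.  Empty cells denote *missing* values (removed by group
cleaning) and are distinct from measured zeros.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGES = ("raw", "thresholded", "corrected", "normalized")

ROW_INDEX_NAMES = ("metabolite", "shift")

#: Fixed column order of differential-result tables.
RESULT_COLUMNS = ("analyte", "estimate", "se", "statistic", "p", "padj")


class DataModelError(ValueError):
    """Raised when an input table violates the data contracts."""


@dataclass(frozen=True)
class MoleculeSpec:
    """A metabolite identity: its key and carbon count.

    ``n_carbons`` is the number of carbon atoms n; the metabolite's
    isotopologues are indexed m+0 ... m+n.
    """

    metabolite_id: str
    n_carbons: int
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise DataModelError(
                f"{self.metabolite_id}: n_carbons must be >= 0, got {self.n_carbons}"
            )


@dataclass
class SampleMeta:
    """Per-sample annotations: celltype group, donor, batch, blank flag.

    Wraps a DataFrame indexed by ``sample_id`` with columns
    ``group``, ``donor``, ``batch``, ``is_blank``.  Blank samples carry a
    batch but need no group/donor.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "donor", "batch", "is_blank"}
        missing = required - set(self.df.columns)
        if missing:
            raise DataModelError(f"sample metadata missing columns: {sorted(missing)}")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()].tolist()
            raise DataModelError(f"duplicate sample ids: {dup}")
        self.df = self.df.copy()
        self.df["is_blank"] = self.df["is_blank"].astype(bool)

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def blank_ids(self) -> pd.Index:
        return self.df.index[self.df["is_blank"]]

    @property
    def biological_ids(self) -> pd.Index:
        return self.df.index[~self.df["is_blank"]]

    def batch_of(self, sample_id: str) -> object:
        return self.df.at[sample_id, "batch"]

    def groups(self) -> pd.Series:
        """Group label per non-blank sample."""
        return self.df.loc[self.biological_ids, "group"]

    def donors(self) -> pd.Series:
        return self.df.loc[self.biological_ids, "donor"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMeta":
        return SampleMeta(self.df.loc[list(sample_ids)])


@dataclass
class IsotopologueTable:
    """Intensity matrix indexed by (metabolite, shift) rows and sample columns.

    ``values`` holds non-negative reals; NaN marks missing entries
    (allowed after group cleaning).  ``stage`` tags the processing state
    and may only advance forward through :data:`STAGES`.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise DataModelError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        idx = self.values.index
        if not isinstance(idx, pd.MultiIndex) or list(idx.names) != list(ROW_INDEX_NAMES):
            raise DataModelError(
                "IsotopologueTable rows must be a (metabolite, shift) MultiIndex"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise DataModelError("negative intensities are not allowed")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index.get_level_values("metabolite").unique())

    def advance(self, values: pd.DataFrame, stage: str) -> "IsotopologueTable":
        """Return a new table at ``stage``, enforcing forward-only transitions."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise DataModelError(f"cannot move stage backwards: {self.stage} -> {stage}")
        return IsotopologueTable(values=values, stage=stage)

    def vector(self, metabolite: str, sample: str) -> pd.Series:
        """The isotopologue vector of one metabolite in one sample, ordered by shift."""
        sub = self.values.xs(metabolite, level="metabolite")[sample]
        return sub.sort_index()

    def select_samples(self, sample_ids: Iterable[str]) -> "IsotopologueTable":
        return replace(self, values=self.values[list(sample_ids)])


@dataclass
class ThresholdSet:
    """Per (metabolite, shift, batch) blank statistics and quantification thresholds.

    ``df`` is indexed by (metabolite, shift, batch) with columns
    ``blank_mean``, ``blank_sd``, ``threshold`` where
    threshold = blank_mean + 2 * blank_sd.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"blank_mean", "blank_sd", "threshold"}
        if not required <= set(self.df.columns):
            raise DataModelError(f"ThresholdSet requires columns {sorted(required)}")
        bad = self.df["threshold"] < self.df["blank_mean"]
        if bad.any():
            raise DataModelError("thresholds below blank means")
        if not np.isfinite(self.df[list(required)].to_numpy()).all():
            raise DataModelError("non-finite threshold statistics")

    def for_batch(self, batch: object) -> pd.DataFrame:
        """Threshold statistics of one batch, indexed by (metabolite, shift)."""
        return self.df.xs(batch, level="batch")

    @property
    def batches(self) -> list[object]:
        return list(self.df.index.get_level_values("batch").unique())


def parse_row_key(key: str, key_sep: str = "_m") -> tuple[str, int]:
    """Split a ``<metabolite><sep><k>`` row key into (metabolite, shift)."""
    m = re.fullmatch(rf"(.+){re.escape(key_sep)}(\d+)", key)
    if m is None:
        raise DataModelError(f"cannot parse row key {key!r} with separator {key_sep!r}")
    return m.group(1), int(m.group(2))


def format_row_key(metabolite: str, shift: int, key_sep: str = "_m") -> str:
    return f"{metabolite}{key_sep}{shift}"


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_molecules(path: str | Path) -> dict[str, MoleculeSpec]:
    """Read a molecule table (metabolite_id, n_carbons, formula) into a dict."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "metabolite_id" not in df.columns or "n_carbons" not in df.columns:
        raise DataModelError("molecule table needs columns metabolite_id, n_carbons")
    if df["metabolite_id"].duplicated().any():
        raise DataModelError("duplicate metabolite_id in molecule table")
    out: dict[str, MoleculeSpec] = {}
    for row in df.itertuples(index=False):
        formula = getattr(row, "formula", None)
        if formula is not None and (pd.isna(formula) or formula == ""):
            formula = None
        out[row.metabolite_id] = MoleculeSpec(
            metabolite_id=row.metabolite_id, n_carbons=int(row.n_carbons), formula=formula
        )
    return out


def write_molecules(molecules: Mapping[str, MoleculeSpec], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "metabolite_id": [m.metabolite_id for m in molecules.values()],
            "n_carbons": [m.n_carbons for m in molecules.values()],
            "formula": [m.formula or "" for m in molecules.values()],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_sample_meta(path: str | Path) -> SampleMeta:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col="sample_id")
    if "is_blank" in df.columns and df["is_blank"].dtype == object:
        df["is_blank"] = (
            df["is_blank"].astype(str).str.strip().str.lower().isin({"true", "1", "yes"})
        )
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    path = Path(path)
    meta.df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_isotopologue_table(
    path: str | Path,
    molecules: Mapping[str, MoleculeSpec],
    key_sep: str = "_m",
    stage: str = "raw",
) -> IsotopologueTable:
    """Read an intensity table whose first column holds ``met_mK`` row keys.

    Rows are validated against ``molecules``: unknown metabolites and
    shifts exceeding the carbon count are rejected, as are duplicate keys
    and negative intensities.  Empty cells become NaN (missing).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    keys = [parse_row_key(str(k), key_sep) for k in df.index]
    seen: set[tuple[str, int]] = set()
    for met, shift in keys:
        if (met, shift) in seen:
            raise DataModelError(f"duplicate row key {format_row_key(met, shift, key_sep)!r}")
        seen.add((met, shift))
        if met not in molecules:
            raise DataModelError(f"unknown metabolite {met!r} in table")
        if shift > molecules[met].n_carbons:
            raise DataModelError(
                f"{met}: shift m+{shift} exceeds n_carbons={molecules[met].n_carbons}"
            )
    idx = pd.MultiIndex.from_tuples(keys, names=ROW_INDEX_NAMES)
    values = pd.DataFrame(df.to_numpy(dtype=float), index=idx, columns=df.columns)
    values = values.sort_index()
    return IsotopologueTable(values=values, stage=stage)


def write_isotopologue_table(
    table: IsotopologueTable, path: str | Path, key_sep: str = "_m"
) -> None:
    path = Path(path)
    out = table.values.copy()
    out.index = [format_row_key(m, k, key_sep) for m, k in out.index]
    out.to_csv(path, sep=_sep_for(path), index_label="isotopologue")


def full_index(molecules: Mapping[str, MoleculeSpec]) -> pd.MultiIndex:
    """The complete (metabolite, shift) index m+0 ... m+n for every metabolite."""
    tuples = [
        (m.metabolite_id, k) for m in molecules.values() for k in range(m.n_carbons + 1)
    ]
    return pd.MultiIndex.from_tuples(tuples, names=ROW_INDEX_NAMES)


def complete_shifts(
    table: IsotopologueTable, molecules: Mapping[str, MoleculeSpec]
) -> tuple[IsotopologueTable, list[str]]:
    """Fill gaps in the shift range of each metabolite with zero rows.

    Returns the completed table and the list of row keys that were added,
    so callers can log them.
    """
    idx = full_index({m: molecules[m] for m in table.metabolites})
    missing = idx.difference(table.values.index)
    if len(missing) == 0:
        return table, []
    filler = pd.DataFrame(0.0, index=missing, columns=table.values.columns)
    values = pd.concat([table.values, filler]).sort_index()
    added = [format_row_key(m, k) for m, k in missing]
    return replace(table, values=values), added


def write_thresholds(thr: ThresholdSet, path: str | Path) -> None:
    """Audit report: one row per (metabolite, shift, batch)."""
    thr.df.to_csv(Path(path), sep="\t")


def write_results(results: pd.DataFrame, directory: str | Path, prefix: str = "results") -> list[Path]:
    """Write one volcano-ready TSV per contrast, rows analyte-sorted.

    ``results`` must carry the columns of :data:`RESULT_COLUMNS` plus a
    ``contrast`` column used to split files.  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if results.empty:
        contrasts: list[str] = []
    else:
        contrasts = list(dict.fromkeys(results["contrast"]))
    for contrast in contrasts or [None]:
        if contrast is None:
            sub = results
            name = f"{prefix}.tsv"
        else:
            sub = results[results["contrast"] == contrast]
            safe = re.sub(r"[^A-Za-z0-9_.-]+", "_", str(contrast))
            name = f"{prefix}_{safe}.tsv"
        out = sub[list(RESULT_COLUMNS)].sort_values("analyte")
        p = directory / name
        out.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
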
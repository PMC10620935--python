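"""Reproducible end-to-end pipeline: threshold → correct → normalize → summarize → test.

A single validated config drives the run; every intermediate table is
written to the output directory together with a machine-readable manifest
(config hash, seed, per-file checksums) so two runs with the same config
and seed are byte-identical and fully traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from . import data_model, normalization, quantification, summaries
from .diffstats import ContrastSpec, DiffConfig, default_contrasts, run_differential_analysis
from .isotope_correction import CorrectionConfig, correct_natural_abundance

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


class ValidationFailure(RuntimeError):
    """Fatal problems found while validating inputs."""


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    table: str
    meta: str
    molecules: str


class CorrectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_nat: float = 0.0107
    tracer_purity: float = 1.0
    solver: Literal["nnls", "direct"] = "nnls"


class NormalizationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weight_clamp_quantile: float = Field(0.99, gt=0.0, le=1.0)


class DiffSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    transform: Literal["log", "linear"] = "log"
    n_quad: int = Field(15, ge=9)
    fdr_family: Literal["per_contrast", "pooled"] = "per_contrast"
    df_method: Literal["t_resid", "z"] = "t_resid"


class ContrastSetting(BaseModel):
    model_config = ConfigDict(extra="forbid")
    plus: str
    minus: str
    label: Optional[str] = None

    def to_spec(self) -> ContrastSpec:
        spec = ContrastSpec.difference(self.plus, self.minus)
        if self.label:
            spec = ContrastSpec(label=self.label, coefficients=spec.coefficients)
        return spec


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    diffstats: bool = True


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    inputs: InputPaths
    output_dir: str
    seed: int = 0
    key_sep: str = "_m"
    stages: StageToggles = StageToggles()
    correction: CorrectionSettings = CorrectionSettings()
    normalization: NormalizationSettings = NormalizationSettings()
    diffstats: DiffSettings = DiffSettings()
    contrasts: Optional[list[ContrastSetting]] = None  # None -> design default

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        The output directory is excluded so that identical analyses
        produce identical manifests wherever they are written.
        """
        payload = self.model_dump(mode="json")
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def validate_inputs(config: RunConfig) -> list[tuple[str, str]]:
    """Check the inputs and return (severity, message) findings.

    ``fatal`` findings make a run impossible (samples missing from the
    metadata, batches without blanks); ``warning`` findings are repaired
    automatically during the run (e.g. gaps in a metabolite's shift
    range, filled with zero rows).
    """
    findings: list[tuple[str, str]] = []
    try:
        molecules = data_model.read_molecules(config.inputs.molecules)
        meta = data_model.read_sample_meta(config.inputs.meta)
        table = data_model.read_isotopologue_table(
            config.inputs.table, molecules, key_sep=config.key_sep
        )
    except Exception as exc:
        return [("fatal", f"cannot read inputs: {exc}")]

    unknown = [s for s in table.values.columns if s not in meta.df.index]
    if unknown:
        findings.append(("fatal", f"samples absent from metadata: {unknown}"))
    batches_seen = {
        meta.df.at[s, "batch"] for s in table.values.columns if s in meta.df.index
    }
    blank_counts = meta.df[meta.df["is_blank"]].groupby("batch").size()
    for batch in sorted(map(str, batches_seen)):
        n = int(blank_counts.get(batch, 0))
        if n == 0:
            findings.append(("fatal", f"batch {batch!r} has no blanks; thresholds impossible"))
        elif n < 2:
            findings.append(("fatal", f"batch {batch!r} has only {n} blank; >=2 required"))
    _, added = data_model.complete_shifts(table, molecules)
    for key in added:
        findings.append(("warning", f"shift gap filled with zero row: {key}"))
    return findings


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every enabled stage, writing intermediates and a manifest.

    Returns the run directory.  A failing stage raises :class:`StageError`
    naming the stage; outputs written before the failure are retained.
    """
    findings = validate_inputs(config)
    fatal = [m for sev, m in findings if sev == "fatal"]
    if fatal:
        raise ValidationFailure("; ".join(fatal))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("midpipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    outputs: dict[str, Path] = {}

    def _run(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    try:
        molecules = data_model.read_molecules(config.inputs.molecules)
        meta = data_model.read_sample_meta(config.inputs.meta)
        raw = data_model.read_isotopologue_table(
            config.inputs.table, molecules, key_sep=config.key_sep
        )
        raw, added = data_model.complete_shifts(raw, molecules)
        if added:
            logger.warning("filled %d shift gaps with zero rows", len(added))

        thr = _run("thresholds", lambda: quantification.compute_blank_thresholds(raw, meta))
        data_model.write_thresholds(thr, out / "thresholds.tsv")
        outputs["thresholds"] = out / "thresholds.tsv"

        thresholded = _run(
            "threshold_correction",
            lambda: quantification.apply_threshold_correction(raw, thr, meta),
        )
        data_model.write_isotopologue_table(thresholded, out / "thresholded.tsv")
        outputs["thresholded"] = out / "thresholded.tsv"

        testable = _run("testable", lambda: quantification.flag_testable(thresholded, thr, meta))
        testable.rename("testable").to_csv(out / "testable.tsv", sep="\t")
        outputs["testable"] = out / "testable.tsv"

        bio = [s for s in thresholded.values.columns if s in set(meta.biological_ids)]

        ccfg = CorrectionConfig(
            p_nat=config.correction.p_nat,
            tracer_purity=config.correction.tracer_purity,
            solver=config.correction.solver,
        )
        corrected = _run(
            "isotope_correction",
            lambda: correct_natural_abundance(
                thresholded.select_samples(bio), molecules, ccfg
            ),
        )
        data_model.write_isotopologue_table(corrected, out / "corrected.tsv")
        outputs["corrected"] = out / "corrected.tsv"

        def _normalize():
            scaled, _ = normalization.normalize_between_isotopologues(corrected)
            sf = normalization.compute_size_factors(
                scaled, weight_clamp_quantile=config.normalization.weight_clamp_quantile
            )
            return normalization.apply_size_factors(scaled, sf), sf

        normalized, sf = _run("normalization", _normalize)
        normalization.write_size_factors(sf, out / "size_factors.tsv")
        outputs["size_factors"] = out / "size_factors.tsv"

        normalized = _run(
            "group_cleaning",
            lambda: quantification.clean_groups(thresholded, thr, meta, target=normalized),
        )
        data_model.write_isotopologue_table(normalized, out / "normalized.tsv")
        outputs["normalized"] = out / "normalized.tsv"

        abundance = _run("summaries", lambda: summaries.metabolite_abundance(normalized))
        mid = summaries.compute_mid(normalized)
        frac = summaries.fractional_labeling(mid, molecules)
        abundance.to_csv(out / "abundance.tsv", sep="\t")
        mid_long = mid.stack(future_stack=True).rename("fraction").reset_index()
        mid_long.columns = ["metabolite", "shift", "sample", "fraction"]
        mid_long.to_csv(out / "mid.tsv", sep="\t", index=False)
        frac.to_csv(out / "fractional_labeling.tsv", sep="\t")
        outputs["abundance"] = out / "abundance.tsv"
        outputs["mid"] = out / "mid.tsv"
        outputs["fractional_labeling"] = out / "fractional_labeling.tsv"

        if config.stages.diffstats:
            contrasts = (
                [c.to_spec() for c in config.contrasts]
                if config.contrasts
                else default_contrasts(meta.groups())
            )
            dcfg = DiffConfig(
                alpha=config.diffstats.alpha,
                transform=config.diffstats.transform,
                n_quad=config.diffstats.n_quad,
                fdr_family=config.diffstats.fdr_family,
                df_method=config.diffstats.df_method,
            )
            results = _run(
                "diffstats",
                lambda: run_differential_analysis(
                    abundance, mid, meta, testable, contrasts, dcfg
                ),
            )
            for level in ("abundance", "isotopologue"):
                written = data_model.write_results(
                    results[level], out, prefix=f"results_{level}"
                )
                for p in written:
                    outputs[p.stem] = p
            results["diagnostics"].to_csv(out / "diagnostics.tsv", sep="\t", index=False)
            outputs["diagnostics"] = out / "diagnostics.tsv"

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages_run": sorted(outputs),
            "checksums": {name: _sha256(path) for name, path in sorted(outputs.items())},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
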
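"""Ground-truthed synthetic ¹³C tracer datasets.

The generator runs the measurement process forwards — the mirror image of
the analysis pipeline's inverse steps — so every stage can be verified
against stored truth:

* per-celltype true MIDs and mean log-abundances, with a donor random
  intercept on the log-abundance scale (paired design: the same donors
  are sampled in every group);
* binomial natural-¹³C convolution using the *same* kernel as the
  corrector (imported from :mod:`midpipe.isotope_correction`, so forward
  and inverse models cannot silently drift apart);
* multiplicative log-normal measurement noise (standard for LC-MS peak
  areas) and an additive Gaussian blank baseline;
* per-sample scale factors and left-censoring near the limit of
  detection;
* blank samples carrying baseline signal only.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import IsotopologueTable, MoleculeSpec, SampleMeta, full_index
from .isotope_correction import NATURAL_13C, CorrectionConfig, build_correction_matrix

PRESETS = ("differentiation", "exhaustion", "null", "lod_stress")


@dataclass
class SimScenario:
    """Full description of one simulated tracer experiment.

    ``group_mids[g][met]`` is the true MID (simplex vector of length
    n_carbons+1) of ``met`` in group ``g``; ``group_log_abundance[g][met]``
    the group-mean natural-log abundance.  ``sigma_donor`` is the SD of
    the donor random intercept on the log-abundance scale; ``noise_cv``
    the coefficient of variation of the multiplicative LC-MS noise.
    """

    molecules: dict[str, MoleculeSpec]
    group_mids: dict[str, dict[str, np.ndarray]]
    group_log_abundance: dict[str, dict[str, float]]
    n_donors: int = 3
    replicates: int = 1
    sigma_donor: float = 0.2
    noise_cv: float = 0.1
    blank_mean: float = 50.0
    blank_sd: float = 10.0
    p_nat: float = NATURAL_13C
    censor_floor: float = 0.0
    scale_sigma: float = 0.0
    sample_scales: dict[str, float] | None = None
    n_blanks: int = 3
    n_batches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for g, mids in self.group_mids.items():
            for met, pi in mids.items():
                pi = np.asarray(pi, dtype=float)
                n = self.molecules[met].n_carbons
                if pi.shape != (n + 1,):
                    raise ValueError(f"{g}/{met}: MID length {pi.shape} != n+1={n+1}")
                if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{g}/{met}: MID not on the simplex: {pi}")
                mids[met] = pi
        if self.sigma_donor < 0 or self.noise_cv < 0 or self.blank_sd < 0:
            raise ValueError("SDs and CV must be >= 0")


@dataclass
class SimTruth:
    """Ground truth stored next to the generated raw tables."""

    true_abundance: pd.DataFrame        # metabolite x sample
    true_mids: pd.DataFrame             # (metabolite, shift) x sample
    abundance_effects: pd.Series        # per metabolite: group means differ?
    fraction_effects: pd.Series         # per (metabolite, shift): fractions differ?
    sample_scales: pd.Series
    donor_effects: pd.DataFrame         # donor x metabolite random intercepts


@dataclass
class SimResult:
    raw: IsotopologueTable              # includes blank columns
    blanks: IsotopologueTable           # blank columns only
    meta: SampleMeta
    truth: SimTruth


def _effect_indicators(sc: SimScenario) -> tuple[pd.Series, pd.Series]:
    mets = list(sc.molecules)
    groups = list(sc.group_mids)
    ab = {}
    for met in mets:
        mus = [sc.group_log_abundance[g][met] for g in groups]
        ab[met] = bool(np.ptp(mus) > 1e-12)
    fr = {}
    for met in mets:
        n = sc.molecules[met].n_carbons
        stacked = np.stack([sc.group_mids[g][met] for g in groups])
        for k in range(n + 1):
            fr[(met, k)] = bool(np.ptp(stacked[:, k]) > 1e-12)
    fr_idx = pd.MultiIndex.from_tuples(fr.keys(), names=("metabolite", "shift"))
    return pd.Series(ab), pd.Series(list(fr.values()), index=fr_idx)


def simulate_experiment(scenario: SimScenario) -> SimResult:
    """Generate raw isotopologue tables, blanks, metadata and truth.

    The returned ``raw`` table contains biological *and* blank columns so
    it can be fed directly to blank thresholding; ``blanks`` is the
    blank-only view.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    mets = list(sc.molecules)
    groups = list(sc.group_mids)
    donors = [f"D{i + 1}" for i in range(sc.n_donors)]

    samples = [
        (g, d, r)
        for g in groups
        for d in donors
        for r in range(1, sc.replicates + 1)
    ]
    sample_ids = [f"{g}_{d}_r{r}" for g, d, r in samples]
    batches = [f"B{i + 1}" for i in range(sc.n_batches)]
    batch_of = {sid: batches[i % sc.n_batches] for i, sid in enumerate(sample_ids)}
    blank_ids = [f"blank_{b}_{i + 1}" for b in batches for i in range(sc.n_blanks)]

    # --- random draws in fixed order ------------------------------------
    donor_fx = rng.normal(0.0, sc.sigma_donor, size=(len(donors), len(mets)))
    if sc.sample_scales is not None:
        scales = np.array([sc.sample_scales[s] for s in sample_ids], dtype=float)
    elif sc.scale_sigma > 0:
        scales = np.exp(rng.normal(0.0, sc.scale_sigma, size=len(sample_ids)))
    else:
        scales = np.ones(len(sample_ids))

    rows = full_index(sc.molecules)
    n_rows = len(rows)
    noise_ln_sd = np.sqrt(np.log1p(sc.noise_cv**2)) if sc.noise_cv > 0 else 0.0

    signal = np.zeros((n_rows, len(sample_ids)))
    truth_ab = pd.DataFrame(
        np.nan, index=pd.Index(mets, name="metabolite"), columns=sample_ids
    )
    truth_mid = pd.DataFrame(np.nan, index=rows, columns=sample_ids)
    group_idx = np.array([groups.index(g) for g, _, _ in samples])
    donor_idx = np.array([donors.index(d) for _, d, _ in samples])

    cfg = CorrectionConfig(p_nat=sc.p_nat)
    row_pos = {key: i for i, key in enumerate(rows)}
    for mi, met in enumerate(mets):
        n = sc.molecules[met].n_carbons
        M = build_correction_matrix(n, cfg)
        mus = np.array([sc.group_log_abundance[groups[gi]][met] for gi in group_idx])
        A = np.exp(mus + donor_fx[donor_idx, mi])
        P = np.stack([sc.group_mids[groups[gi]][met] for gi in group_idx], axis=1)
        V = P * A[None, :]
        X = M @ V
        sl = slice(row_pos[(met, 0)], row_pos[(met, 0)] + n + 1)
        signal[sl, :] = X
        truth_ab.loc[met] = A
        truth_mid.iloc[sl.start : sl.stop] = P

    if noise_ln_sd > 0:
        signal = signal * np.exp(
            rng.normal(0.0, noise_ln_sd, size=signal.shape)
        )
    baseline = np.clip(
        rng.normal(sc.blank_mean, sc.blank_sd, size=signal.shape), 0.0, None
    )
    signal = (signal + baseline) * scales[None, :]
    if sc.censor_floor > 0:
        signal[signal < sc.censor_floor] = 0.0

    blank_vals = np.clip(
        rng.normal(sc.blank_mean, sc.blank_sd, size=(n_rows, len(blank_ids))),
        0.0,
        None,
    )
    if sc.censor_floor > 0:
        blank_vals[blank_vals < sc.censor_floor] = 0.0

    values = pd.DataFrame(
        np.hstack([signal, blank_vals]), index=rows, columns=sample_ids + blank_ids
    )
    raw = IsotopologueTable(values=values, stage="raw")
    blanks = IsotopologueTable(values=values[blank_ids].copy(), stage="raw")

    meta_rows = []
    for (g, d, _), sid in zip(samples, sample_ids):
        meta_rows.append((sid, g, d, batch_of[sid], False))
    for bid in blank_ids:
        meta_rows.append((bid, "", "", bid.split("_")[1], True))
    meta = SampleMeta(
        pd.DataFrame(
            meta_rows, columns=["sample_id", "group", "donor", "batch", "is_blank"]
        ).set_index("sample_id")
    )

    ab_fx, fr_fx = _effect_indicators(sc)
    truth = SimTruth(
        true_abundance=truth_ab,
        true_mids=truth_mid,
        abundance_effects=ab_fx,
        fraction_effects=fr_fx,
        sample_scales=pd.Series(scales, index=sample_ids),
        donor_effects=pd.DataFrame(donor_fx, index=donors, columns=mets),
    )
    return SimResult(raw=raw, blanks=blanks, meta=meta, truth=truth)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _simplex(*parts: float) -> np.ndarray:
    """A MID with the remainder of the mass on m+0."""
    v = np.array(parts, dtype=float)
    if v.sum() > 1.0 + 1e-12:
        raise ValueError("fractions exceed 1")
    v[0] = 1.0 - v[1:].sum()
    return v


#: Glycolysis/TCA panel plus stable free amino acids.  The amino acids are
#: unlabeled and constant in every group: glucose carbon does not reach
#: them on the experiment's time scale, and their presence keeps the
#: changed metabolites a minority, as size-factor normalization assumes.
_PANEL = {
    "3pg": 3, "pep": 3, "pyr": 3, "lac": 3, "ala": 3,
    "cit": 6, "akg": 5, "glu": 5, "suc": 4, "fum": 4, "mal": 4, "asp": 4,
    "gly": 2, "ser": 3, "thr": 4, "asn": 4, "pro": 5, "gln": 5,
    "val": 5, "leu": 6, "ile": 6, "lys": 6, "arg": 6, "his": 6,
}
_LABELED = ("3pg", "pep", "pyr", "lac", "ala", "cit", "akg", "glu",
            "suc", "fum", "mal", "asp")


def _panel_molecules() -> dict[str, MoleculeSpec]:
    return {m: MoleculeSpec(m, n) for m, n in _PANEL.items()}


def _tca_mid(n: int, m2: float, m3: float) -> np.ndarray:
    """m+2-dominant TCA labeling with a smaller anaplerotic m+3 component."""
    v = np.zeros(n + 1)
    v[1] = 0.02
    v[2] = m2
    v[3] = m3
    v[0] = 1.0 - v[1:].sum()
    return v


def _differentiation_scenario(seed: int) -> SimScenario:
    molecules = _panel_molecules()
    e0 = {m: _simplex(*([0.0] * (n + 1))) for m, n in _PANEL.items()}

    # TN: glycolysis blocked below 3pg -> label reaches 3pg but nothing downstream
    tn = dict(e0)
    tn["3pg"] = np.array([0.40, 0.0, 0.0, 0.60])

    def activated() -> dict[str, np.ndarray]:
        mids = dict(e0)
        mids["3pg"] = np.array([0.25, 0.0, 0.0, 0.75])
        for m in ("pep", "pyr", "lac", "ala"):
            mids[m] = np.array([0.35, 0.02, 0.03, 0.60])
        for m in ("cit", "akg", "glu", "suc", "fum", "mal", "asp"):
            # anaplerotic/oxidative ratio m+3/m+2 = 0.15
            mids[m] = _tca_mid(_PANEL[m], 0.36, 0.15 * 0.36)
        return mids

    act = activated()
    group_mids = {
        "TN": tn,
        "TSCM": {m: v.copy() for m, v in act.items()},
        "TCM": {m: v.copy() for m, v in act.items()},
        "TEM": {m: v.copy() for m, v in act.items()},
    }

    base = float(np.log(2e5))
    mu: dict[str, dict[str, float]] = {g: {} for g in group_mids}
    # balanced per-step abundance effects in a minority of metabolites
    effect_mets = {"lac": 0.5, "suc": -0.4, "mal": 0.35, "cit": -0.3}
    order = ["TN", "TSCM", "TCM", "TEM"]
    for m in _PANEL:
        for gi, g in enumerate(order):
            step = effect_mets.get(m, 0.0)
            mu[g][m] = base + step * gi
    return SimScenario(
        molecules=molecules,
        group_mids=group_mids,
        group_log_abundance=mu,
        n_donors=3,
        replicates=2,
        sigma_donor=0.2,
        noise_cv=0.1,
        blank_mean=50.0,
        blank_sd=10.0,
        censor_floor=1.0,
        seed=seed,
    )


def _exhaustion_scenario(seed: int) -> SimScenario:
    molecules = _panel_molecules()
    eff = {
        m: (
            np.array([0.30, 0.02, 0.03, 0.65])
            if n == 3
            else _tca_mid(n, 0.40, 0.06)
        )
        if m in _LABELED
        else _simplex(*([0.0] * (n + 1)))
        for m, n in _PANEL.items()
    }
    ex = {
        m: (
            np.array([0.55, 0.02, 0.03, 0.40])
            if n == 3
            else _tca_mid(n, 0.22, 0.033)
        )
        if m in _LABELED
        else _simplex(*([0.0] * (n + 1)))
        for m, n in _PANEL.items()
    }
    base = float(np.log(2e5))
    mu = {
        "TEFF": {m: base for m in _PANEL},
        "TEX": {m: base - (0.5 if m in ("suc", "fum", "mal") else 0.0) for m in _PANEL},
    }
    return SimScenario(
        molecules=molecules,
        group_mids={"TEFF": eff, "TEX": ex},
        group_log_abundance=mu,
        n_donors=3,
        replicates=2,
        sigma_donor=0.2,
        noise_cv=0.1,
        censor_floor=1.0,
        seed=seed,
    )


def _null_scenario(seed: int, n_metabolites: int = 1000) -> SimScenario:
    """No group effects anywhere: shared MIDs and abundances, 2 groups.

    24 samples (2 groups x 3 donors x 4 replicates) give the group
    contrast enough residual degrees of freedom for the normal
    approximation of the Wald test to be accurate.
    """
    rng = np.random.default_rng(seed + 101)
    molecules = {f"met{i:04d}": MoleculeSpec(f"met{i:04d}", 3) for i in range(n_metabolites)}
    mids = {}
    mus = {}
    for m in molecules:
        p = rng.dirichlet([8.0, 2.0, 2.0, 2.0])
        mids[m] = p
        mus[m] = float(np.log(2e5) + rng.normal(0.0, 0.5))
    return SimScenario(
        molecules=molecules,
        group_mids={"A": dict(mids), "B": {m: v.copy() for m, v in mids.items()}},
        group_log_abundance={"A": dict(mus), "B": dict(mus)},
        n_donors=3,
        replicates=4,
        sigma_donor=0.2,
        noise_cv=0.15,
        blank_mean=50.0,
        blank_sd=10.0,
        censor_floor=1.0,
        seed=seed,
    )


def _lod_stress_scenario(seed: int) -> SimScenario:
    """Abundances straddling the blank threshold to exercise group cleaning."""
    rng = np.random.default_rng(seed + 202)
    molecules = {f"met{i:02d}": MoleculeSpec(f"met{i:02d}", 3) for i in range(30)}
    mids = {m: np.array([0.55, 0.05, 0.1, 0.3]) for m in molecules}
    mus_a = {m: float(np.log(2000.0) + rng.normal(0.0, 1.5)) for m in molecules}
    mus_b = {m: v + 0.3 for m, v in mus_a.items()}
    return SimScenario(
        molecules=molecules,
        group_mids={"A": dict(mids), "B": {m: v.copy() for m, v in mids.items()}},
        group_log_abundance={"A": mus_a, "B": mus_b},
        n_donors=3,
        replicates=2,
        sigma_donor=0.2,
        noise_cv=0.2,
        blank_mean=1000.0,
        blank_sd=250.0,
        censor_floor=1.0,
        seed=seed,
    )


def scenario_to_dict(sc: SimScenario) -> dict:
    """YAML/JSON-serializable form of a scenario (MIDs as lists)."""
    return {
        "molecules": {
            m: {"n_carbons": spec.n_carbons, "formula": spec.formula}
            for m, spec in sc.molecules.items()
        },
        "group_mids": {
            g: {m: [float(v) for v in pi] for m, pi in mids.items()}
            for g, mids in sc.group_mids.items()
        },
        "group_log_abundance": {
            g: {m: float(v) for m, v in mus.items()}
            for g, mus in sc.group_log_abundance.items()
        },
        "n_donors": sc.n_donors,
        "replicates": sc.replicates,
        "sigma_donor": sc.sigma_donor,
        "noise_cv": sc.noise_cv,
        "blank_mean": sc.blank_mean,
        "blank_sd": sc.blank_sd,
        "p_nat": sc.p_nat,
        "censor_floor": sc.censor_floor,
        "scale_sigma": sc.scale_sigma,
        "sample_scales": sc.sample_scales,
        "n_blanks": sc.n_blanks,
        "n_batches": sc.n_batches,
        "seed": sc.seed,
    }


def scenario_from_dict(payload: dict) -> SimScenario:
    """Inverse of :func:`scenario_to_dict`; validates via SimScenario."""
    payload = dict(payload)
    molecules = {
        m: MoleculeSpec(m, int(v["n_carbons"]), v.get("formula"))
        for m, v in payload.pop("molecules").items()
    }
    group_mids = {
        g: {m: np.asarray(pi, dtype=float) for m, pi in mids.items()}
        for g, mids in payload.pop("group_mids").items()
    }
    return SimScenario(molecules=molecules, group_mids=group_mids, **payload)


def contrast_effects(
    sc: SimScenario, plus: str, minus: str, tol: float = 1e-12
) -> tuple[pd.Series, pd.Series]:
    """Ground-truth effect indicators for one group contrast.

    Returns (abundance_effects, fraction_effects): per metabolite and per
    (metabolite, shift), True where the two groups' true values differ.
    """
    ab = {}
    fr = {}
    for met in sc.molecules:
        ab[met] = bool(
            abs(sc.group_log_abundance[plus][met] - sc.group_log_abundance[minus][met])
            > tol
        )
        d = np.abs(sc.group_mids[plus][met] - sc.group_mids[minus][met])
        for k, dk in enumerate(d):
            fr[(met, k)] = bool(dk > tol)
    fr_idx = pd.MultiIndex.from_tuples(fr.keys(), names=("metabolite", "shift"))
    return pd.Series(ab), pd.Series(list(fr.values()), index=fr_idx)


def scenario_presets(name: str, seed: int = 0, **overrides) -> SimScenario:
    """Named study designs: differentiation, exhaustion, null, lod_stress.

    ``overrides`` are forwarded to scenario construction where supported
    (e.g. ``n_metabolites`` for the null preset) or replace scalar fields.
    """
    builders = {
        "differentiation": _differentiation_scenario,
        "exhaustion": _exhaustion_scenario,
        "null": _null_scenario,
        "lod_stress": _lod_stress_scenario,
    }
    if name not in builders:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    ctor_kwargs = {}
    if name == "null" and "n_metabolites" in overrides:
        ctor_kwargs["n_metabolites"] = overrides.pop("n_metabolites")
    sc = builders[name](seed, **ctor_kwargs)
    for key, value in overrides.items():
        if not hasattr(sc, key):
            raise ValueError(f"unknown scenario field {key!r}")
        setattr(sc, key, value)
    return sc
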
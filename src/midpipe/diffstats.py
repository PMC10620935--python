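"""Differential testing of metabolite abundances and isotopologue fractions.

Abundances are compared on the natural-log scale in a linear mixed model
with celltype as fixed effect and donor as random intercept (REML).
Isotopologue fractions, being proportions, are modeled with beta
regression on the logit scale with the same donor random intercept
(maximum likelihood, adaptive Gauss-Hermite quadrature).  Group-level
contrasts (e.g. TSCM - TN) are tested with Wald z statistics and the
p-values are Benjamini-Hochberg adjusted across analytes within each
contrast family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .betamix import BetaMixedResult, fit_beta_mixed
from .data_model import RESULT_COLUMNS, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class DiffConfig:
    """Knobs of the differential-testing stage."""

    alpha: float = 0.05
    transform: str = "log"          # abundance transform: "log" or "linear"
    n_quad: int = 15                # Gauss-Hermite nodes for the beta model
    fdr_family: str = "per_contrast"  # or "pooled" across contrasts
    df_method: str = "t_resid"      # Wald reference: t on residual df, or "z"


@dataclass(frozen=True)
class ContrastSpec:
    """A linear combination of fixed-effect (group) levels.

    ``coefficients`` maps level -> weight; difference contrasts sum to 0.
    ``family`` groups contrasts for FDR adjustment (defaults to the label).
    """

    label: str
    coefficients: dict[str, float] = field(hash=False)
    family: str | None = None

    @classmethod
    def difference(cls, plus: str, minus: str) -> "ContrastSpec":
        return cls(label=f"{plus}-{minus}", coefficients={plus: 1.0, minus: -1.0})

    @property
    def family_id(self) -> str:
        return self.family or self.label


@dataclass
class LmmFit:
    """REML fit of log-abundance ~ group + (1 | donor)."""

    params: pd.Series            # group-level means on the model scale
    cov_params: pd.DataFrame
    sigma_d2: float              # donor random-intercept variance
    sigma_e2: float              # residual variance
    loglik: float
    converged: bool
    n_obs: int
    df_resid: float = np.inf    # residual df for the t reference of Wald tests
    message: str = ""


def default_contrasts(groups) -> list[ContrastSpec]:
    """Consecutive-subset contrasts for the standard designs.

    Differentiation panels (TN, TSCM, TCM, TEM) get the three consecutive
    differences; exhaustion panels (TEFF, TEX) get TEX - TEFF; any other
    design falls back to consecutive differences in order of appearance.
    """
    levels = list(dict.fromkeys(groups))
    if {"TN", "TSCM", "TCM", "TEM"} <= set(levels):
        order = ["TN", "TSCM", "TCM", "TEM"]
        return [ContrastSpec.difference(b, a) for a, b in zip(order, order[1:])]
    if {"TEFF", "TEX"} <= set(levels):
        return [ContrastSpec.difference("TEX", "TEFF")]
    return [ContrastSpec.difference(b, a) for a, b in zip(levels, levels[1:])]


def _constant_fit(levels: list[str], value: float, n_obs: int) -> LmmFit:
    zeros = pd.DataFrame(0.0, index=levels, columns=levels)
    return LmmFit(
        params=pd.Series(value, index=levels),
        cov_params=zeros,
        sigma_d2=0.0,
        sigma_e2=0.0,
        loglik=np.nan,
        converged=True,
        n_obs=n_obs,
        df_resid=np.inf,
        message="constant response",
    )


def _log_with_offset(y: pd.Series) -> tuple[pd.Series, float]:
    """Natural log; zeros handled by adding half the analyte's smallest positive value."""
    offset = 0.0
    if (y == 0).any():
        positive = y[y > 0]
        if positive.empty:
            raise ValueError("all-zero abundances cannot be log-transformed")
        offset = 0.5 * float(positive.min())
    return np.log(y + offset), offset


def fit_abundance_lmm(
    abundance: pd.DataFrame,
    meta: SampleMeta,
    metabolite: str,
    config: DiffConfig = DiffConfig(),
) -> LmmFit:
    """Fit log(abundance) ~ 0 + group + (1 | donor) by REML for one metabolite.

    Group-level coefficients are the group means on the model scale, so
    contrast vectors act on them directly.  Non-convergence is flagged
    rather than raised; the analyte is later reported with a missing p.
    """
    y = abundance.loc[metabolite, meta.biological_ids.intersection(abundance.columns)]
    y = y.dropna()
    groups = meta.df.loc[y.index, "group"].astype(str)
    donors = meta.df.loc[y.index, "donor"].astype(str)
    counts = groups.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            f"{metabolite}: need >=2 groups with >=2 samples, have {counts.to_dict()}"
        )
    levels = sorted(counts.index)
    if config.transform == "log":
        y, _ = _log_with_offset(y)
    if float(np.ptp(y.to_numpy())) == 0.0:
        return _constant_fit(levels, float(y.iloc[0]), len(y))
    exog = pd.get_dummies(groups, dtype=float)[levels]
    exog.columns.name = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM(y.to_numpy(), exog.to_numpy(), groups=donors.to_numpy())
        res = None
        failure = ""
        # boundary fits (sigma_d -> 0) often need a derivative-free retry
        for method in (None, "powell", "nm"):
            try:
                res = (
                    model.fit(reml=True)
                    if method is None
                    else model.fit(reml=True, method=method, maxiter=2000)
                )
            except Exception as exc:
                failure = f"fit failed: {exc}"
                res = None
                continue
            if res.converged:
                break
        if res is None:
            return LmmFit(
                params=pd.Series(np.nan, index=levels),
                cov_params=pd.DataFrame(np.nan, index=levels, columns=levels),
                sigma_d2=np.nan,
                sigma_e2=np.nan,
                loglik=np.nan,
                converged=False,
                n_obs=len(y),
                message=failure,
            )
    cov_fe = pd.DataFrame(
        np.asarray(res.cov_params())[: len(levels), : len(levels)],
        index=levels,
        columns=levels,
    )
    df_resid = float(max(len(y) - len(levels) - (donors.nunique() - 1), 1))
    return LmmFit(
        params=pd.Series(res.fe_params, index=levels),
        cov_params=cov_fe,
        sigma_d2=float(np.asarray(res.cov_re).ravel()[0]),
        sigma_e2=float(res.scale),
        loglik=float(res.llf),
        converged=bool(res.converged),
        n_obs=len(y),
        df_resid=df_resid,
    )


def fit_mid_betareg(
    mid: pd.DataFrame,
    meta: SampleMeta,
    metabolite: str,
    shift: int,
    config: DiffConfig = DiffConfig(),
) -> BetaMixedResult:
    """Beta mixed regression of one isotopologue's fraction on celltype.

    Boundary fractions are shrunk into (0, 1); the donor random intercept
    is integrated out by adaptive Gauss-Hermite quadrature.
    """
    row = mid.loc[(metabolite, shift)]
    y = row[meta.biological_ids.intersection(row.index)].dropna()
    groups = meta.df.loc[y.index, "group"].astype(str)
    donors = meta.df.loc[y.index, "donor"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError(f"{metabolite} m+{shift}: need >=2 groups")
    yv = y.to_numpy(dtype=float)
    if float(np.ptp(yv)) == 0.0 and 0.0 < yv[0] < 1.0:
        zeros = pd.DataFrame(0.0, index=levels, columns=levels)
        eta = float(scipy.special.logit(yv[0]))
        return BetaMixedResult(
            params=pd.Series(eta, index=levels),
            phi=np.inf,
            sigma_d=0.0,
            cov_params=zeros,
            loglik=np.nan,
            converged=True,
            n_obs=len(yv),
            message="constant response",
        )
    exog = pd.get_dummies(groups, dtype=float)[levels]
    return fit_beta_mixed(yv, exog, donors.to_numpy(), n_quad=config.n_quad)


def _wald_row(
    fit, contrast: ContrastSpec, df_method: str = "t_resid"
) -> tuple[float, float, float, float]:
    levels = list(fit.params.index)
    missing = [l for l in contrast.coefficients if l not in levels]
    if missing:
        raise KeyError(f"contrast {contrast.label!r} references absent level(s) {missing}")
    c = np.array([contrast.coefficients.get(l, 0.0) for l in levels])
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.cov_params.to_numpy() @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        return est, se, 0.0, 1.0
    z = est / se
    df = getattr(fit, "df_resid", np.inf)
    if df_method == "t_resid" and np.isfinite(df):
        p = 2.0 * scipy.stats.t.sf(abs(z), df)
    else:
        p = 2.0 * scipy.stats.norm.sf(abs(z))
    return est, se, z, p


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """BH-adjusted p-values; NaNs are excluded and stay NaN."""
    out = pd.Series(np.nan, index=p.index, dtype=float)
    mask = p.notna()
    if mask.any():
        out[mask] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    return out


def test_contrasts(
    fits: dict[str, object],
    contrasts: list[ContrastSpec],
    fdr_family: str = "per_contrast",
    df_method: str = "t_resid",
) -> pd.DataFrame:
    """Wald tests of every contrast on every fitted analyte, BH-adjusted.

    ``fits`` maps analyte id -> LmmFit or BetaMixedResult.  Non-converged
    or degenerate fits are reported with missing estimates/p-values.  FDR
    adjustment runs across analytes, within each contrast family
    (``per_contrast``) or pooled over all contrasts (``pooled``).
    """
    rows = []
    for analyte, fit in fits.items():
        for contrast in contrasts:
            usable = getattr(fit, "converged", False) and not getattr(
                fit, "degenerate", False
            )
            if usable:
                try:
                    est, se, z, p = _wald_row(fit, contrast, df_method)
                except KeyError:
                    # a contrast level was removed for this analyte (e.g. by
                    # group cleaning): report the row with missing values
                    logger.warning(
                        "%s: contrast %s references a level absent from the fit",
                        analyte,
                        contrast.label,
                    )
                    est = se = z = p = np.nan
            else:
                est = se = z = p = np.nan
            rows.append(
                {
                    "analyte": analyte,
                    "contrast": contrast.label,
                    "family": contrast.family_id,
                    "estimate": est,
                    "se": se,
                    "statistic": z,
                    "p": p,
                }
            )
    res = pd.DataFrame(
        rows, columns=["analyte", "contrast", "family", "estimate", "se", "statistic", "p"]
    )
    if res.empty:
        res["padj"] = pd.Series(dtype=float)
        return res[list(RESULT_COLUMNS) + ["contrast", "family"]]
    if fdr_family == "pooled":
        res["padj"] = benjamini_hochberg(res["p"])
    else:
        res["padj"] = (
            res.groupby("family", group_keys=False)["p"].apply(benjamini_hochberg)
        )
    return res


def run_differential_analysis(
    abundance: pd.DataFrame,
    mid: pd.DataFrame,
    meta: SampleMeta,
    testable: pd.Series,
    contrasts: list[ContrastSpec] | None = None,
    config: DiffConfig = DiffConfig(),
) -> dict[str, pd.DataFrame]:
    """Abundance-level and isotopologue-level differential results.

    A metabolite enters the abundance analysis when at least one of its
    isotopologues is testable; an isotopologue enters the fraction
    analysis when itself testable and its MID defined somewhere.  Returns
    ``{"abundance": ..., "isotopologue": ..., "diagnostics": ...}``;
    abundance and isotopologue families are FDR-adjusted separately.
    """
    if contrasts is None:
        contrasts = default_contrasts(meta.groups())
    if not contrasts:
        empty = pd.DataFrame(columns=list(RESULT_COLUMNS) + ["contrast", "family"])
        return {"abundance": empty, "isotopologue": empty.copy(), "diagnostics": pd.DataFrame()}

    diag_rows = []
    ab_fits: dict[str, object] = {}
    testable_mets = testable[testable].index.get_level_values("metabolite").unique()
    for met in abundance.index:
        if met not in set(testable_mets):
            continue
        try:
            fit = fit_abundance_lmm(abundance, meta, met, config)
        except ValueError as exc:
            logger.warning("abundance LMM skipped for %s: %s", met, exc)
            continue
        ab_fits[met] = fit
        diag_rows.append(
            {
                "analyte": met,
                "level": "abundance",
                "converged": fit.converged,
                "var_donor": fit.sigma_d2,
                "var_resid_or_phi": fit.sigma_e2,
                "loglik": fit.loglik,
                "n_obs": fit.n_obs,
            }
        )

    iso_fits: dict[str, object] = {}
    for met, shift in testable[testable].index:
        if (met, shift) not in mid.index:
            continue
        if mid.loc[(met, shift)].dropna().empty:
            continue
        try:
            fit = fit_mid_betareg(mid, meta, met, shift, config)
        except ValueError as exc:
            logger.warning("beta regression skipped for %s m+%d: %s", met, shift, exc)
            continue
        analyte = f"{met}_m{shift}"
        iso_fits[analyte] = fit
        diag_rows.append(
            {
                "analyte": analyte,
                "level": "isotopologue",
                "converged": fit.converged,
                "var_donor": fit.sigma_d**2 if np.isfinite(fit.sigma_d) else np.nan,
                "var_resid_or_phi": fit.phi,
                "loglik": fit.loglik,
                "n_obs": fit.n_obs,
            }
        )

    return {
        "abundance": test_contrasts(ab_fits, contrasts, config.fdr_family, config.df_method),
        "isotopologue": test_contrasts(
            iso_fits, contrasts, config.fdr_family, config.df_method
        ),
        "diagnostics": pd.DataFrame(diag_rows),
    }
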
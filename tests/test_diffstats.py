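import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from midpipe import diffstats as ds

from conftest import make_meta


def _paired_meta(groups=("TN", "TSCM"), donors=("D1", "D2", "D3"), reps=2):
    rows = []
    for g in groups:
        for d in donors:
            for r in range(1, reps + 1):
                rows.append((f"{g}_{d}_r{r}", g, d, "B1", False))
    return make_meta(rows)


def _abundance_frame(meta, values):
    return pd.DataFrame([values], index=["met"], columns=meta.biological_ids)


class TestAbundanceLmm:
    def test_zero_donor_variance_matches_ols_group_means(self):
        """Without donor variability the REML fixed effects are the
        ordinary least-squares solution, i.e. the group means of log y."""
        meta = _paired_meta(reps=3)
        rng = np.random.default_rng(0)
        # donor-free data: same generative law for every donor
        y = np.exp(rng.normal(5.0, 0.1, size=len(meta.biological_ids)))
        ab = _abundance_frame(meta, y)
        fit = ds.fit_abundance_lmm(ab, meta, "met")
        logy = pd.Series(np.log(y), index=meta.biological_ids)
        groups = meta.df.loc[logy.index, "group"]
        ols = logy.groupby(groups).mean()
        assert fit.converged
        assert np.allclose(fit.params[ols.index], ols, atol=1e-6)

    def test_constant_response_gives_zero_difference_p_one(self):
        meta = _paired_meta()
        ab = _abundance_frame(meta, np.full(len(meta.biological_ids), 7.0))
        fit = ds.fit_abundance_lmm(ab, meta, "met")
        res = ds.test_contrasts({"met": fit}, [ds.ContrastSpec.difference("TSCM", "TN")])
        assert res["estimate"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_zero_offset_applied_for_log(self):
        meta = _paired_meta()
        vals = np.linspace(1.0, 2.0, len(meta.biological_ids))
        vals[0] = 0.0
        ab = _abundance_frame(meta, vals)
        fit = ds.fit_abundance_lmm(ab, meta, "met")  # must not raise on the zero
        assert fit.n_obs == len(vals)

    def test_requires_two_groups_with_two_samples(self):
        meta = _paired_meta(groups=("TN",))
        ab = _abundance_frame(meta, np.ones(len(meta.biological_ids)))
        with pytest.raises(ValueError, match="need >=2 groups"):
            ds.fit_abundance_lmm(ab, meta, "met")

    def test_estimate_within_three_se_of_truth(self):
        hits = 0
        n_sim = 50
        for i in range(n_sim):
            rng = np.random.default_rng(3000 + i)
            meta = _paired_meta(reps=2)
            delta = 0.8
            mu = {"TN": 5.0, "TSCM": 5.0 + delta}
            donor_fx = dict(zip(["D1", "D2", "D3"], rng.normal(0, 0.3, 3)))
            y = []
            for s in meta.biological_ids:
                g = meta.df.at[s, "group"]
                d = meta.df.at[s, "donor"]
                y.append(np.exp(mu[g] + donor_fx[d] + rng.normal(0, 0.2)))
            ab = _abundance_frame(meta, np.array(y))
            fit = ds.fit_abundance_lmm(ab, meta, "met")
            res = ds.test_contrasts(
                {"met": fit}, [ds.ContrastSpec.difference("TSCM", "TN")]
            )
            est, se = res["estimate"].iloc[0], res["se"].iloc[0]
            if abs(est - delta) <= 3 * se:
                hits += 1
        assert hits / n_sim >= 0.9


class TestContrasts:
    def _fit(self, params, cov=None, df=np.inf):
        levels = list(params)
        cov = pd.DataFrame(
            cov if cov is not None else np.eye(len(levels)) * 0.01,
            index=levels,
            columns=levels,
        )
        return ds.LmmFit(
            params=pd.Series(params),
            cov_params=cov,
            sigma_d2=0.0,
            sigma_e2=1.0,
            loglik=0.0,
            converged=True,
            n_obs=10,
            df_resid=df,
        )

    def test_zero_contrast_vector_gives_p_one(self):
        fit = self._fit({"A": 1.0, "B": 2.0})
        c = ds.ContrastSpec(label="null", coefficients={"A": 0.0, "B": 0.0})
        res = ds.test_contrasts({"m": fit}, [c])
        assert res["estimate"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_single_analyte_padj_equals_p(self):
        fit = self._fit({"A": 1.0, "B": 2.0})
        res = ds.test_contrasts({"m": fit}, [ds.ContrastSpec.difference("B", "A")])
        assert res["padj"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_bh_by_hand_on_three_pvalues(self):
        padj = ds.benjamini_hochberg(pd.Series([0.01, 0.02, 0.9]))
        assert np.allclose(padj, [0.03, 0.03, 0.9])

    def test_absent_level_reported_missing(self):
        fit = self._fit({"A": 1.0, "B": 2.0})
        res = ds.test_contrasts({"m": fit}, [ds.ContrastSpec.difference("C", "A")])
        assert res["p"].isna().all()

    def test_empty_contrast_list_gives_empty_results(self):
        fits = {"m": self._fit({"A": 1.0, "B": 2.0})}
        res = ds.test_contrasts(fits, [])
        assert res.empty

    def test_t_reference_is_more_conservative_than_z(self):
        fit = self._fit({"A": 0.0, "B": 0.3}, df=10)
        c = [ds.ContrastSpec.difference("B", "A")]
        p_t = ds.test_contrasts({"m": fit}, c, df_method="t_resid")["p"].iloc[0]
        p_z = ds.test_contrasts({"m": fit}, c, df_method="z")["p"].iloc[0]
        assert p_t > p_z

    @given(
        p=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_bh_properties(self, p):
        padj = ds.benjamini_hochberg(pd.Series(p, dtype=float))
        assert (padj <= 1.0 + 1e-12).all()
        assert (padj.to_numpy() >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert np.all(np.diff(padj.to_numpy()[order]) >= -1e-12)


class TestDefaultContrasts:
    def test_differentiation_design(self):
        labels = [c.label for c in ds.default_contrasts(["TN", "TSCM", "TCM", "TEM"])]
        assert labels == ["TSCM-TN", "TCM-TSCM", "TEM-TCM"]

    def test_exhaustion_design(self):
        labels = [c.label for c in ds.default_contrasts(["TEFF", "TEX"])]
        assert labels == ["TEX-TEFF"]

    def test_generic_fallback_consecutive(self):
        labels = [c.label for c in ds.default_contrasts(["A", "B", "C"])]
        assert labels == ["B-A", "C-B"]
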
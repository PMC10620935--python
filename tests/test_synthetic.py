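import numpy as np
import pandas as pd
import pytest

from midpipe import normalization as nz
from midpipe import quantification as q
from midpipe import summaries as sm
from midpipe.data_model import MoleculeSpec
from midpipe.isotope_correction import correct_natural_abundance
from midpipe.synthetic import (
    SimScenario,
    scenario_from_dict,
    scenario_presets,
    scenario_to_dict,
    simulate_experiment,
)


def _noise_free_scenario(seed=0):
    mols = {"lac": MoleculeSpec("lac", 3), "cit": MoleculeSpec("cit", 6)}
    mids = {
        "lac": np.array([0.3, 0.05, 0.05, 0.6]),
        "cit": np.array([0.4, 0.02, 0.4, 0.06, 0.08, 0.02, 0.02]),
    }
    mu = {"lac": np.log(1e5), "cit": np.log(5e4)}
    return SimScenario(
        molecules=mols,
        group_mids={"A": {k: v.copy() for k, v in mids.items()}, "B": {k: v.copy() for k, v in mids.items()}},
        group_log_abundance={"A": dict(mu), "B": dict(mu)},
        n_donors=2,
        replicates=2,
        sigma_donor=0.0,
        noise_cv=0.0,
        blank_mean=0.0,
        blank_sd=0.0,
        censor_floor=0.0,
        seed=seed,
    )


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        a = simulate_experiment(scenario_presets("differentiation", seed=5))
        b = simulate_experiment(scenario_presets("differentiation", seed=5))
        pd.testing.assert_frame_equal(a.raw.values, b.raw.values)
        pd.testing.assert_frame_equal(a.truth.true_abundance, b.truth.true_abundance)

    def test_different_seed_differs(self):
        a = simulate_experiment(scenario_presets("differentiation", seed=5))
        b = simulate_experiment(scenario_presets("differentiation", seed=6))
        assert not a.raw.values.equals(b.raw.values)


class TestForwardInverseConsistency:
    def test_noise_free_pipeline_recovers_true_mids(self):
        """With no noise, baseline or donor effects, thresholding is inert
        and the corrector inverts the forward convolution exactly."""
        sc = _noise_free_scenario()
        sim = simulate_experiment(sc)
        thr = q.compute_blank_thresholds(sim.raw, sim.meta)
        t = q.apply_threshold_correction(sim.raw, thr, sim.meta)
        bio = list(sim.meta.biological_ids)
        corr = correct_natural_abundance(t.select_samples(bio), sc.molecules)
        scaled, _ = nz.normalize_between_isotopologues(corr)
        mid = sm.compute_mid(scaled)
        for met in sc.molecules:
            got = mid.loc[met][bio].to_numpy()
            want = sc.group_mids["A"][met][:, None] * np.ones((1, len(bio)))
            assert np.allclose(got, want, atol=1e-6)

    def test_true_abundance_recovered_noise_free(self):
        sc = _noise_free_scenario()
        sim = simulate_experiment(sc)
        bio = list(sim.meta.biological_ids)
        corr = correct_natural_abundance(
            sim.raw.advance(sim.raw.values[bio], "thresholded"), sc.molecules
        )
        ab = sm.metabolite_abundance(corr)
        pd.testing.assert_frame_equal(
            ab.sort_index(),
            sim.truth.true_abundance[bio].sort_index(),
            atol=1e-6,
            check_exact=False,
        )


class TestStatisticalStructure:
    def test_donor_intraclass_correlation(self):
        mols = {"m": MoleculeSpec("m", 1)}
        sigma_d, cv = 0.4, 0.2
        sc = SimScenario(
            molecules=mols,
            group_mids={"A": {"m": np.array([1.0, 0.0])}},
            group_log_abundance={"A": {"m": np.log(1e5)}},
            n_donors=15,
            replicates=12,
            sigma_donor=sigma_d,
            noise_cv=cv,
            blank_mean=0.0,
            blank_sd=0.0,
            seed=9,
        )
        sim = simulate_experiment(sc)
        logy = np.log(sim.truth.true_abundance.loc["m"])
        obs = np.log(
            sim.raw.values.loc["m"].sum(axis=0)[sim.meta.biological_ids]
        )
        donors = sim.meta.donors()
        groups = obs.groupby(donors)
        k = 12
        msb = k * groups.mean().var(ddof=1)
        msw = groups.var(ddof=1).mean()
        icc = (msb - msw) / (msb + (k - 1) * msw)
        sigma_ln2 = np.log1p(cv**2)
        expected = sigma_d**2 / (sigma_d**2 + sigma_ln2)
        assert icc == pytest.approx(expected, abs=0.12)

    def test_blank_statistics_match_configuration(self):
        sc = scenario_presets("differentiation", seed=2)
        sc.n_blanks = 40
        sim = simulate_experiment(sc)
        blanks = sim.blanks.values.to_numpy().ravel()
        assert np.mean(blanks) == pytest.approx(sc.blank_mean, rel=0.05)
        assert np.std(blanks) == pytest.approx(sc.blank_sd, rel=0.15)


class TestPresets:
    def test_differentiation_labeling_pattern(self):
        sc = scenario_presets("differentiation", seed=0)
        assert np.allclose(sc.group_mids["TN"]["lac"], [1.0, 0.0, 0.0, 0.0])
        assert sc.group_mids["TSCM"]["lac"][3] > 0.5
        sim = simulate_experiment(sc)
        # truth tables carry the same pattern
        assert sim.truth.true_mids.loc[("lac", 3), "TN_D1_r1"] == 0.0
        assert sim.truth.true_mids.loc[("lac", 3), "TSCM_D1_r1"] > 0.5

    def test_differentiation_tca_ratio(self):
        sc = scenario_presets("differentiation", seed=0)
        for met in ("cit", "suc", "fum", "mal"):
            pi = sc.group_mids["TEM"][met]
            assert pi[3] / pi[2] == pytest.approx(0.15)

    def test_null_preset_has_no_effects(self):
        sc = scenario_presets("null", seed=0, n_metabolites=20)
        sim = simulate_experiment(sc)
        assert not sim.truth.abundance_effects.any()
        assert not sim.truth.fraction_effects.any()

    def test_lod_stress_exercises_cleaning(self):
        sc = scenario_presets("lod_stress", seed=0)
        sim = simulate_experiment(sc)
        thr = q.compute_blank_thresholds(sim.raw, sim.meta)
        t = q.apply_threshold_correction(sim.raw, thr, sim.meta)
        bio = list(sim.meta.biological_ids)
        tmat = q._threshold_matrix(t, thr, sim.meta, bio)
        below = (t.values[bio] < tmat).to_numpy().mean()
        assert below >= 0.2
        cleaned = q.clean_groups(t, thr, sim.meta)
        assert cleaned.values[bio].isna().any().any()

    def test_scenario_dict_roundtrip_preserves_data(self):
        sc = scenario_presets("exhaustion", seed=3)
        back = scenario_from_dict(scenario_to_dict(sc))
        a = simulate_experiment(sc)
        b = simulate_experiment(back)
        pd.testing.assert_frame_equal(a.raw.values, b.raw.values)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            scenario_presets("nonsense")

    def test_invalid_simplex_rejected(self):
        mols = {"m": MoleculeSpec("m", 1)}
        with pytest.raises(ValueError, match="simplex"):
            SimScenario(
                molecules=mols,
                group_mids={"A": {"m": np.array([0.7, 0.6])}},
                group_log_abundance={"A": {"m": 1.0}},
            )
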
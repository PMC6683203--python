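"""Generator behaviour: fates, traits, mating structure, missingness, I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit
from scipy.stats import truncnorm

import sublethal as sl
from sublethal.blocks import GEN2_BLOCKS


def _zeroed_survival(params: sl.ParameterSet,
                     overrides: dict | None = None) -> sl.ParameterSet:
    """Copy of ``params`` with every mortality coefficient set to zero."""
    out = params.copy()
    for name, bdef in sl.BLOCKS.items():
        if bdef.family == "mortality":
            for term in bdef.covariates:
                out.blocks[name][term] = 0.0
    if overrides:
        out = out.updated(overrides)
    return out


def _emerged_gen2_frame(n: int, sex="female", within="control",
                        trans="control", maternal_mass=165.0) -> pd.DataFrame:
    """Gen-2 survivors of every stage, with fixed covariates."""
    return pd.DataFrame({
        "id": [f"X{i}" for i in range(n)],
        "generation": np.full(n, 2),
        "within_treatment": within,
        "maternal_treatment": trans,
        "sex": sex,
        "maternal_mass10_mg": float(maternal_mass),
        "died_24h": 0.0, "died_larval": 0.0, "died_pupal": 0.0,
        "died_adult": 0.0,
    })


class TestSimulateGen1:
    def test_degenerate_no_death_limit(self, published_design, ref_params, rng):
        """Mortality intercepts at -inf give zero death probability."""
        params = ref_params.copy()
        for name in ("g1_surv_24h", "g1_surv_larval", "g1_surv_pupal",
                     "g1_surv_adult"):
            params.blocks[name]["intercept"] = -np.inf
            for term in sl.BLOCKS[name].covariates[1:]:
                params.blocks[name][term] = 0.0
        cohort = sl.cohort_to_frame(sl.simulate_gen1(published_design, params, rng))
        for col in ("died_24h", "died_larval", "died_pupal", "died_adult"):
            assert (cohort[col] == 0.0).all()
        # every survivor carries the full trait record
        assert cohort["dev_time_days"].notna().all()
        assert cohort["mass_day10_mg"].notna().all()

    def test_24h_survival_matches_closed_form_average(self, ref_params, rng):
        """Control-arm 24 h survival converges to the expit average over the
        pre-treatment mass distribution."""
        design = sl.CohortDesign(n_gen1_larvae=100_000)
        cohort = sl.cohort_to_frame(sl.simulate_gen1(design, ref_params, rng))
        ctrl = cohort[cohort["within_treatment"] == "control"]
        surv = float((ctrl["died_24h"] == 0.0).mean())

        b = ref_params.blocks["g1_surv_24h"]
        a_trunc = (0.0 - design.larval_mass_mean_mg) / design.larval_mass_sd_mg
        grid = np.linspace(1e-6, 12.0, 4001)
        dens = truncnorm.pdf(grid, a_trunc, np.inf,
                             loc=design.larval_mass_mean_mg,
                             scale=design.larval_mass_sd_mg)
        p_surv = 1.0 - expit(b["intercept"] + b["larval_mass"] * grid)
        expected = np.trapezoid(p_surv * dens, grid) / np.trapezoid(dens, grid)
        se = np.sqrt(expected * (1 - expected) / len(ctrl))
        assert abs(surv - expected) < 3 * se

    def test_emergence_mass_sex_difference(self, ref_params, rng):
        """With no treatment effect, expected emergence mass is the intercept
        for females and intercept + male coefficient for males
        (122.77 vs 104.39 mg at the published values)."""
        params = ref_params.updated({"g1_mass_emergence:within": 0.0})
        n = 20_000
        frame = pd.DataFrame({
            "id": [f"A{i}" for i in range(n)],
            "generation": np.ones(n, dtype=int),
            "within_treatment": "control",
            "sex": np.where(np.arange(n) % 2 == 0, "male", "female"),
            "died_24h": 0.0, "died_larval": 0.0, "died_pupal": 0.0,
        })
        sim = sl.resimulate(frame, params, rng, blocks=["g1_mass_emergence"])
        male = sim.loc[sim["sex"] == "male", "mass_emergence_mg"]
        female = sim.loc[sim["sex"] == "female", "mass_emergence_mg"]
        tol = 3 * params.scale("g1_mass_emergence") / np.sqrt(n / 2)
        assert abs(male.mean() - 104.39) < tol
        assert abs(female.mean() - 122.77) < tol


class TestMateDesign:
    def test_paper_defaults_give_56_families(self, published_cohort, published_design,
                                             rng):
        families = sl.mate_design(published_cohort, published_design, rng)
        assert len(families) == 56
        trts = pd.Series([f.maternal_treatment for f in families])
        assert (trts.value_counts() == 28).all()
        sires = {f.sire_id for f in families}
        assert len(sires) == 14

    def test_minimal_split(self, published_cohort, rng):
        design = sl.CohortDesign(n_sires=1, dams_per_sire=2)
        families = sl.mate_design(published_cohort, design, rng)
        assert len(families) == 2
        assert {f.maternal_treatment for f in families} == \
            {"control", "insecticide"}

    def test_shortfall_error_reports_counts(self, published_cohort, published_design,
                                            rng):
        """With too few insecticide dams the error states the need (28)."""
        frame = published_cohort.copy()
        g1_ins_females = (frame["generation"] == 1) & \
            (frame["sex"] == "female") & \
            (frame["within_treatment"] == "insecticide")
        keep = frame.index[g1_ins_females][:20]
        drop = frame.index[g1_ins_females].difference(keep)
        frame = frame.drop(index=drop)
        with pytest.raises(sl.ShortfallError) as err:
            sl.mate_design(frame, published_design, rng)
        assert err.value.needed == 28
        assert "28" in str(err.value)

    def test_sires_are_control_males(self, published_cohort, published_design, rng):
        families = sl.mate_design(published_cohort, published_design, rng)
        g1 = published_cohort.set_index("id")
        for fam in families:
            assert g1.loc[fam.sire_id, "within_treatment"] == "control"
            assert g1.loc[fam.sire_id, "sex"] == "male"
            assert g1.loc[fam.dam_id, "sex"] == "female"


class TestSimulateGen2:
    def test_intercept_zero_gives_half_death(self, ref_params, rng):
        """expit(0) = 0.5: zeroed total-larval block kills half the cohort."""
        params = _zeroed_survival(ref_params)
        frame = _emerged_gen2_frame(20_000)
        sim = sl.resimulate(frame, params, rng, blocks=["g2_surv_larval"])
        rate = float((sim["died_larval"] == 1.0).mean())
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / len(frame))

    def test_lipid_intercept_mean(self, ref_params, rng):
        """Female control lipid fraction has mean expit(-1.42) = 0.195."""
        frame = _emerged_gen2_frame(20_000)
        sim = sl.resimulate(frame, ref_params, rng, blocks=["g2_lipid"])
        mu = expit(-1.42)  # maternal-mass slope is 0 at the published values
        phi = ref_params.scale("g2_lipid")
        se = np.sqrt(mu * (1 - mu) / (1 + phi) / len(frame))
        assert abs(sim["lipid_frac"].mean() - mu) < max(3 * se, 2e-3)

    def test_maternal_exposure_survival_odds_ratio(self, ref_params, rng):
        """With the published transgenerational coefficient -0.56, offspring
        of exposed dams have 1.75x the larval survival odds (Monte Carlo vs
        closed form at 1e5 per arm)."""
        params = _zeroed_survival(
            ref_params, {"g2_surv_larval:intercept": 0.51,
                         "g2_surv_larval:trans": -0.56})
        n = 100_000
        frames = {t: _emerged_gen2_frame(n, trans=t)
                  for t in ("control", "insecticide")}
        odds = {}
        for trt, frame in frames.items():
            sim = sl.resimulate(frame, params, rng, blocks=["g2_surv_larval"])
            p_surv = float((sim["died_larval"] == 0.0).mean())
            odds[trt] = p_surv / (1.0 - p_surv)
        ratio = odds["insecticide"] / odds["control"]
        assert abs(ratio - np.exp(0.56)) < 0.06

    def test_offspring_inherit_family_covariates(self, published_cohort):
        g2 = published_cohort[published_cohort["generation"] == 2]
        assert len(g2) == 842
        assert g2["family_id"].nunique() == 56
        counts = g2["family_id"].value_counts()
        assert counts.max() - counts.min() <= 1       # near-uniform allocation
        g1 = published_cohort[published_cohort["generation"] == 1].set_index("id")
        mothers = g2["mother_id"].unique()
        assert all(g1.loc[m, "sex"] == "female" for m in mothers)
        # offspring of a dam with a recorded mass carry exactly that mass
        merged = g2.join(g1["mass_day10_mg"].rename("dam_mass"),
                         on="mother_id")
        recorded = merged["dam_mass"].notna()
        assert np.allclose(merged.loc[recorded, "maternal_mass10_mg"],
                           merged.loc[recorded, "dam_mass"])
        assert merged.loc[~recorded, "maternal_mass10_mg"].isna().all()


class TestMissingness:
    def test_earliest_death_blanks_everything_later(self):
        ind = sl.Individual(
            id="x", generation=1, within_treatment="insecticide",
            larval_mass_mg=4.2, died_24h=True, died_larval=False, sex="male",
            dev_time_days=29.0, mass_emergence_mg=120.0, mass_day10_mg=150.0)
        out = sl.apply_missingness([ind])[0]
        assert out.died_24h is True
        assert out.larval_mass_mg == 4.2
        for field in ("died_larval", "died_pupal", "died_adult", "sex",
                      "dev_time_days", "mass_emergence_mg", "mass_day10_mg"):
            assert getattr(out, field) is None

    def test_complete_case_untouched(self, published_cohort):
        g2 = published_cohort[published_cohort["generation"] == 2]
        alive = g2[(g2["died_adult"] == 0.0) &
                   g2["maternal_mass10_mg"].notna()]
        assert len(alive) > 0
        assert alive[["sex", "dev_time_days", "mass_emergence_mg",
                      "mass_day14_mg", "lipid_frac", "water_frac",
                      "drymass_frac", "fresh_mg", "dry_mg",
                      "lean_mg"]].notna().all().all()

    @given(seed=st.integers(0, 50))
    def test_idempotent_on_simulated_cohorts(self, seed):
        design = sl.CohortDesign(n_gen1_larvae=60, n_sires=2, dams_per_sire=2,
                                 n_gen2_larvae=40)
        params = sl.reference_parameters()
        try:
            individuals, _ = sl.simulate_cohort(design, params, seed=seed,
                                                max_attempts=1)
        except sl.ShortfallError:
            return
        frame = sl.cohort_to_frame(individuals)
        once = sl.apply_missingness(frame)
        twice = sl.apply_missingness(once)
        pd.testing.assert_frame_equal(once, twice)


class TestInvariants:
    def test_stage_conservation(self, published_cohort):
        """Per stage: survivors + deaths = entrants; entrants of stage k are
        the survivors of stage k-1."""
        for gen in (1, 2):
            sub = published_cohort[published_cohort["generation"] == gen]
            entrants = len(sub)
            for col in ("died_24h", "died_larval", "died_pupal", "died_adult"):
                defined = sub[col].notna().sum()
                assert defined == entrants
                deaths = (sub[col] == 1.0).sum()
                survivors = (sub[col] == 0.0).sum()
                assert deaths + survivors == entrants
                entrants = survivors

    def test_raising_death_logit_never_increases_survival(self, published_design,
                                                          ref_params):
        """Common-random-number coupling: a larger treatment coefficient in
        the first-stage death logit can only add deaths in the exposed arm."""
        hi = ref_params.updated({"g1_surv_24h:within": 3.0})
        a = sl.cohort_to_frame(sl.simulate_gen1(published_design, ref_params,
                                                np.random.default_rng(5)))
        b = sl.cohort_to_frame(sl.simulate_gen1(published_design, hi,
                                                np.random.default_rng(5)))
        died_low = a["died_24h"] == 1.0
        died_high = b["died_24h"] == 1.0
        assert (died_high | ~died_low).all()          # died_low => died_high
        assert died_high.sum() >= died_low.sum()

    def test_folch_weight_ordering(self, published_cohort):
        g2 = published_cohort[published_cohort["fresh_mg"].notna()]
        assert (g2["lean_mg"] <= g2["dry_mg"] + 1e-9).all()
        assert (g2["dry_mg"] <= g2["fresh_mg"] + 1e-9).all()
        assert np.allclose(
            sl.lipid_fraction(g2["fresh_mg"], g2["dry_mg"], g2["lean_mg"]),
            np.minimum(g2["lipid_frac"], g2["drymass_frac"]), atol=1e-9)
        assert np.allclose(sl.drymass_fraction(g2["fresh_mg"], g2["dry_mg"]),
                           g2["drymass_frac"])
        for col in ("lipid_frac", "water_frac", "drymass_frac"):
            vals = published_cohort[col].dropna()
            assert ((vals > 0) & (vals < 1)).all()


class TestCohortCsv:
    def test_round_trip_is_lossless(self, published_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        sl.write_cohort(path, published_cohort)
        back = sl.read_cohort(path)
        pd.testing.assert_frame_equal(published_cohort.reset_index(drop=True),
                                      back, check_dtype=False,
                                      check_exact=True)

    def test_missing_column_raises_schema_error(self, published_cohort, tmp_path):
        path = tmp_path / "broken.csv"
        published_cohort.drop(columns=["died_pupal"]).to_csv(path, index=False)
        with pytest.raises(sl.SchemaError, match="died_pupal"):
            sl.read_cohort(path)

    def test_design_sidecar_round_trip(self, small_design, ref_params,
                                       tmp_path):
        path = tmp_path / "design.yaml"
        sl.cohort.write_design_sidecar(path, small_design, ref_params, seed=7)
        design, params, seed = sl.cohort.read_design_sidecar(path)
        assert design == small_design
        assert seed == 7
        assert params.flatten() == ref_params.flatten()


class TestDesignValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_gen1_larvae": 0},
        {"dams_per_sire": 3},
        {"treatment_allocation": 0.0},
        {"treatment_allocation": 1.0},
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(sl.ConfigurationError):
            dataclasses.replace(sl.CohortDesign(), **kwargs).validate()

    def test_incomplete_params_name_the_block(self, published_design, rng):
        params = sl.reference_parameters()
        del params.blocks["g1_surv_pupal"]
        with pytest.raises(sl.ConfigurationError, match="g1_surv_pupal"):
            sl.simulate_gen1(published_design, params, rng)
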
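"""Synthetic survey generator: cell probabilities, sampling, microdata, recovery."""

import numpy as np
import pytest

from carequity.loglinear import GeneratingClass, Term, backward_select, ipf_fit
from carequity.pipeline import categorize_respondents, utilization_table
from carequity.ses import cronbach_alpha
from carequity.synthetic import (
    GenerativeSpec,
    MicrodataSpec,
    cell_probabilities,
    dummy_lambda,
    survey_like_spec,
    sample_microdata,
    sample_table,
)
from carequity.tables import CategoricalAxis

X2 = CategoricalAxis("x", ("x1", "x2"))
Y2 = CategoricalAxis("y", ("y1", "y2"))
Z3 = CategoricalAxis("z", ("z1", "z2", "z3"))


def simple_spec(lam_xy=np.log(2.0)):
    return GenerativeSpec(
        axes=(X2, Y2),
        generating_class=GeneratingClass([["x", "y"]]),
        lambdas={Term(["x", "y"]): dummy_lambda((2, 2), [[lam_xy]])},
    )


class TestCellProbabilities:
    def test_no_lambdas_give_uniform(self):
        spec = GenerativeSpec(
            axes=(X2, Z3),
            generating_class=GeneratingClass([["x"], ["z"]]),
            lambdas={},
        )
        p = cell_probabilities(spec)
        np.testing.assert_allclose(p.counts, 1 / 6)
        assert p.total == pytest.approx(1.0)

    def test_single_two_way_lambda_sets_cell_or(self):
        p = cell_probabilities(simple_spec(np.log(2.0))).counts
        assert (p[0, 0] * p[1, 1]) / (p[0, 1] * p[1, 0]) == pytest.approx(2.0)

    def test_conditional_ors_match_lambda_contrasts(self):
        """Brute-force contrast check on a three-axis spec with interactions."""
        lam_xz = np.array([[0.4, -0.2], [0.0, 0.0]])  # (x levels-1 x z levels-1) block
        spec = GenerativeSpec(
            axes=(X2, Y2, Z3),
            generating_class=GeneratingClass([["x", "z"], ["y"]]),
            lambdas={
                Term(["x"]): dummy_lambda((2,), [0.3]),
                Term(["z"]): dummy_lambda((3,), [0.1, -0.5]),
                Term(["x", "z"]): dummy_lambda((2, 3), lam_xz[:1]),
            },
        )
        p = cell_probabilities(spec).counts
        # OR between x=x1 (vs ref x2) and z=z_k (vs ref z3) at any y
        for k, expected in [(0, np.exp(0.4)), (1, np.exp(-0.2))]:
            orat = (p[0, 0, k] * p[1, 0, 2]) / (p[1, 0, k] * p[0, 0, 2])
            assert orat == pytest.approx(expected, rel=1e-12)

    def test_dummy_coding_requires_zero_reference(self):
        bad = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="reference"):
            GenerativeSpec(
                axes=(X2, Y2),
                generating_class=GeneratingClass([["x", "y"]]),
                lambdas={Term(["x", "y"]): bad},
            )

    def test_yaml_round_trip(self):
        spec = survey_like_spec()
        back = GenerativeSpec.from_yaml(spec.to_yaml())
        assert back.generating_class == spec.generating_class
        np.testing.assert_allclose(
            cell_probabilities(back).counts, cell_probabilities(spec).counts
        )


class TestSampleTable:
    def test_single_draw_and_determinism(self):
        spec = simple_spec()
        one = sample_table(spec, 1, seed=5)
        assert one.total == 1
        assert np.count_nonzero(one.counts) == 1
        a = sample_table(spec, 500, seed=11)
        b = sample_table(spec, 500, seed=11)
        assert a == b
        c = sample_table(spec, 500, seed=12)
        assert a != c

    def test_uniform_proportions_within_binomial_bound(self):
        spec = GenerativeSpec(
            axes=(X2, Y2, Z3),
            generating_class=GeneratingClass([["x"], ["y"], ["z"]]),
            lambdas={},
        )
        n = 200_000
        table = sample_table(spec, n, seed=3)
        p = 1 / 12
        bound = 4 * np.sqrt(p * (1 - p) / n)
        np.testing.assert_array_less(np.abs(table.counts / n - p), bound)


@pytest.fixture(scope="module")
def default_draw():
    spec = survey_like_spec()
    return spec, sample_microdata(spec, 30_000, seed=17, include_truth=True)


class TestMicrodata:
    def test_alpha_lands_in_target_band(self, default_draw):
        _, df = default_draw
        _, meta = categorize_respondents(df)
        assert 0.6 <= meta.alpha <= 0.8

    def test_zero_correlation_target_drops_alpha_to_structural_floor(self):
        """With no shared latent trait only the mechanical SEC overlap between the
        cluster item and the ln(rooms*SEC) housing item keeps alpha above zero."""
        spec = survey_like_spec(MicrodataSpec(item_correlation=0.0))
        df = sample_microdata(spec, 20_000, seed=23)
        from carequity.ses import DEFAULT_BINNING, calibrate_rooms, categorize_item, rooms_item

        occ = df.occupation.map(lambda c: categorize_item(c, DEFAULT_BINNING.occupation))
        edu = df.education.map(lambda c: categorize_item(c, DEFAULT_BINNING.education))
        sec = df.sec.map(lambda c: categorize_item(c, DEFAULT_BINNING.sec))
        calib = calibrate_rooms(df.rooms.to_numpy(), df.sec.to_numpy())
        rooms = rooms_item(df.rooms.to_numpy(), df.sec.to_numpy(), calib)
        matrix = np.column_stack([occ, edu, sec, rooms])
        alpha = cronbach_alpha(matrix).alpha
        assert alpha < 0.3  # far below the default band [0.6, 0.8]
        corr = np.corrcoef(matrix, rowvar=False)
        off = corr[~np.eye(4, dtype=bool)]
        # every pair except cluster-vs-housing is uncorrelated
        assert np.sort(np.abs(off))[:-2].max() < 0.05

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            MicrodataSpec(item_correlation=1.0)

    def test_location_conditional_low_ses_share_matches_config(self, default_draw):
        spec, df = default_draw
        mix = spec.microdata.location_ses_mix
        for code, loc in [(1, "peripheral"), (2, "intermediate"), (3, "central")]:
            share = (df.loc[df.location == code, "ses_true"] == "low").mean()
            assert share == pytest.approx(mix[loc][0], abs=0.03)

    def test_visit_flags_consistent_with_counts(self, default_draw):
        _, df = default_draw
        assert ((df.gp_visits > 0) == (df.vis_gp == "yes")).all()
        assert ((df.sd_visits > 0) == (df.vis_sd == "yes")).all()

    def test_raw_codes_within_survey_ranges(self, default_draw):
        _, df = default_draw
        assert df.occupation.between(1, 11).all()
        assert df.education.between(0, 6).all()
        assert df.sec.between(1, 10).all()
        assert df.rooms.between(0.5, 9.5).all()
        assert ((df.rooms * 2) % 1 == 0).all()


class TestEndToEnd:
    def test_pipeline_recovers_generative_or_directions(self):
        """Microdata -> SES index -> crosstab -> fit: pro-poor elderly GP use and
        pro-rich young specialist use, as built into the generative truth."""
        spec = survey_like_spec()
        df = sample_microdata(spec, 40_000, seed=31)
        categorized, meta = categorize_respondents(df)
        table = utilization_table(categorized)
        assert table.total == len(categorized)

        gp = table.collapse(["location", "age", "ses", "vis_gp"])
        fit = ipf_fit(gp, GeneratingClass([["location", "age", "ses"], ["age", "ses", "vis_gp"]]))
        from carequity.effects import EffectQuery, conditional_odds_ratio

        elderly_gp = conditional_odds_ratio(
            fit,
            EffectQuery("vis_gp", "ses", ("low", "high"), fixed={"age": "ge60"}),
        )
        assert elderly_gp.value > 1.15  # pro-poor, attenuated by tertile reclassification

        sd = table.collapse(["location", "age", "ses", "vis_sd"])
        fit_sd = ipf_fit(sd, GeneratingClass(
            [["location", "vis_sd"], ["location", "age", "ses"], ["age", "ses", "vis_sd"]]
        ))
        young_sd = conditional_odds_ratio(
            fit_sd,
            EffectQuery("vis_sd", "ses", ("low", "high"), fixed={"age": "lt60"}),
        )
        assert young_sd.value < 0.85  # pro-rich


class TestRecovery:
    def test_parameter_recovery_within_monte_carlo_error(self):
        """Fitted conditional ORs track exp(lambda) across 20 multinomial draws."""
        lam = np.log(1.8)
        spec = GenerativeSpec(
            axes=(X2, Y2, Z3),
            generating_class=GeneratingClass([["x", "y"], ["z"]]),
            lambdas={
                Term(["x"]): dummy_lambda((2,), [-0.4]),
                Term(["y"]): dummy_lambda((2,), [0.6]),
                Term(["x", "y"]): dummy_lambda((2, 2), [[lam]]),
            },
        )
        gc = spec.generating_class
        log_ors = []
        for seed in range(20):
            table = sample_table(spec, 50_000, seed=100 + seed)
            fit = ipf_fit(table, gc)
            f = fit.fitted.counts
            log_ors.append(
                np.log((f[0, 0, 0] * f[1, 1, 0]) / (f[1, 0, 0] * f[0, 1, 0]))
            )
        log_ors = np.asarray(log_ors)
        mc_se = log_ors.std(ddof=1) / np.sqrt(len(log_ors))
        assert abs(log_ors.mean() - lam) <= 3 * mc_se

    def test_selection_recovers_generative_class(self):
        """Backward elimination finds the true class in >=90% of 50 replicates."""
        spec = GenerativeSpec(
            axes=(X2, Y2, Z3),
            generating_class=GeneratingClass([["x", "y"], ["x", "z"], ["y", "z"]]),
            lambdas={
                Term(["x"]): dummy_lambda((2,), [0.2]),
                Term(["z"]): dummy_lambda((3,), [0.1, -0.2]),
                Term(["x", "y"]): dummy_lambda((2, 2), [[0.5]]),
                Term(["x", "z"]): dummy_lambda((2, 3), [[0.4, -0.35]]),
                Term(["y", "z"]): dummy_lambda((2, 3), [[-0.45, 0.3]]),
            },
        )
        hits = sum(
            backward_select(sample_table(spec, 50_000, seed=1000 + r)).final_class
            == spec.generating_class
            for r in range(50)
        )
        assert hits >= 45
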
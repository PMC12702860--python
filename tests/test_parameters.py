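"""Parameter registry: validation, distribution assignment, conversions, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preterm_bia import (
    Parameter,
    ParameterError,
    assign_distribution,
    charge_to_cost,
    cost_to_charge,
    default_fixture,
    inflate_to_2024,
    load_parameters,
    perturb,
    sample,
)
from preterm_bia.parameters import Family, Kind, dump_parameters


def make(kind="probability", value=0.5, frac=0.1, **kw):
    kw.setdefault("period_days", 365.0 if kind in ("probability", "rate") else None)
    return Parameter(name="x", value=value, kind=kind, uncertainty_frac=frac, **kw)


class TestValidation:
    def test_probability_out_of_bounds_rejected(self):
        # pydantic surfaces the bounds violation as a ValidationError (a ValueError)
        with pytest.raises(ValueError, match="bounds"):
            make(value=1.2)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            make(kind="cost", value=-5.0)

    def test_missing_mandatory_parameter_named_in_error(self, fixture_ps):
        doc = {"parameters": {
            n: {"value": p.value, "kind": p.kind.value,
                **({"period_days": p.period_days} if p.period_days else {}),
                **({"bounds": list(p.bounds)} if p.bounds else {})}
            for n, p in fixture_ps.parameters.items() if n != "ttd"
        }}
        with pytest.raises(ParameterError, match="ttd"):
            load_parameters(doc)

    def test_out_of_bounds_value_in_file_reported_with_name(self, fixture_ps):
        import yaml

        doc = yaml.safe_load(dump_parameters(fixture_ps))
        doc["parameters"]["prop_nns_at_birth"]["value"] = 1.2
        with pytest.raises(ParameterError, match="prop_nns_at_birth"):
            load_parameters(doc)

    def test_missing_file_errors(self):
        with pytest.raises(ParameterError, match="no_such_file"):
            load_parameters("no_such_file.yaml")

    def test_fixture_loads_with_expected_cohort_size(self, fixture_ps):
        assert fixture_ps.n_patients == 100


class TestDistributionAssignment:
    @pytest.mark.parametrize(
        "kind,value,family",
        [
            ("probability", 0.50, Family.normal),
            ("probability", 0.10, Family.normal),
            ("probability", 0.90, Family.normal),
            ("probability", 0.05, Family.beta),
            ("probability", 0.95, Family.beta),
            ("cost", 1000.0, Family.gamma),
            ("charge", 1000.0, Family.gamma),
            ("odds_ratio", 2.0, Family.lognormal),
            ("rate", 0.3, Family.normal),
            ("factor", 0.8, Family.normal),
        ],
    )
    def test_family_rules(self, kind, value, family):
        assert assign_distribution(make(kind=kind, value=value)).family is family

    def test_zero_uncertainty_is_degenerate(self):
        spec = assign_distribution(make(frac=0.0))
        assert spec.family is Family.degenerate
        rng = np.random.default_rng(0)
        assert spec.draw(rng) == 0.5

    def test_normal_moments(self):
        spec = assign_distribution(make(value=0.5, frac=0.1))
        assert spec.mean == 0.5 and spec.sd == pytest.approx(0.05)

    def test_pure_function_of_inputs(self):
        a = assign_distribution(make(value=0.3, frac=0.1, note="a"))
        b = assign_distribution(make(value=0.3, frac=0.1, note="b"))
        assert a == b

    @pytest.mark.parametrize(
        "kind,value,frac",
        [("cost", 1000.0, 0.2), ("probability", 0.05, 0.1),
         ("odds_ratio", 2.0, 0.1), ("probability", 0.5, 0.1)],
    )
    def test_moment_matching_by_monte_carlo(self, kind, value, frac):
        """Sampled mean ~ base value and sd ~ value*frac for every family."""
        spec = assign_distribution(make(kind=kind, value=value, frac=frac))
        draws = spec.draw(np.random.default_rng(7), size=50_000)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - value) < 4 * se
        assert draws.std(ddof=1) == pytest.approx(value * frac, rel=0.05)

    def test_gamma_shape_scale_closed_form(self):
        # mean 1000, frac 0.2 -> shape 1/0.04 = 25, scale mean/shape = 40
        spec = assign_distribution(make(kind="cost", value=1000.0, frac=0.2))
        shape = (spec.mean / spec.sd) ** 2
        assert shape == pytest.approx(25.0)
        assert spec.sd == pytest.approx(200.0)

    def test_probability_draws_respect_unit_interval(self):
        spec = assign_distribution(make(value=0.95, frac=0.1))
        draws = spec.draw(np.random.default_rng(3), size=20_000)
        assert draws.min() >= 0.0 and draws.max() <= 1.0


class TestConversions:
    def test_charge_to_cost_definition(self):
        assert charge_to_cost(1000.0, 0.5) == 500.0
        assert charge_to_cost(0.0, 0.5) == 0.0
        assert charge_to_cost(123.0, 1.0) == 123.0

    def test_bad_ratio_rejected(self):
        with pytest.raises(ParameterError):
            charge_to_cost(100.0, 0.0)

    @given(st.floats(0.01, 1e6), st.floats(0.05, 1.5))
    def test_roundtrip_identity(self, charge, ratio):
        assert cost_to_charge(charge_to_cost(charge, ratio), ratio) == pytest.approx(
            charge, rel=1e-12
        )

    def test_inflation_same_year_identity(self):
        assert inflate_to_2024(100.0, 2024, {2024: 1.0}) == 100.0

    def test_inflation_ratio(self):
        idx = {2020: 1.0, 2024: 1.2}
        assert inflate_to_2024(100.0, 2020, idx) == pytest.approx(120.0)
        assert inflate_to_2024(100.0, 2020, {2020: 1.0, 2024: 2.0}) == pytest.approx(200.0)

    def test_missing_year_named(self):
        with pytest.raises(ParameterError, match="2019"):
            inflate_to_2024(100.0, 2019, {2024: 1.0})

    def test_loader_normalizes_monetary_years(self, fixture_ps):
        import yaml

        doc = yaml.safe_load(dump_parameters(fixture_ps))
        doc["parameters"]["nicu_charge_per_day"].update(value=1000.0, year_of_value=2020)
        ps = load_parameters(doc)
        idx = ps.inflation_index
        assert ps.value("nicu_charge_per_day") == pytest.approx(1000.0 * idx[2024] / idx[2020])
        assert ps["nicu_charge_per_day"].year_of_value == 2024


class TestPerturbAndSample:
    def test_perturb_touches_only_target(self, fixture_ps):
        out = perturb(fixture_ps, "nicu_charge_per_day", 1.2)
        assert out.value("nicu_charge_per_day") == pytest.approx(
            1.2 * fixture_ps.value("nicu_charge_per_day")
        )
        for name in fixture_ps.names():
            if name != "nicu_charge_per_day":
                assert out.value(name) == fixture_ps.value(name)

    def test_perturb_identity_factor(self, fixture_ps):
        out = perturb(fixture_ps, "ttd", 1.0)
        assert out.value("ttd") == fixture_ps.value("ttd")

    def test_perturb_clamps_probabilities(self, fixture_ps):
        out = perturb(fixture_ps, "prop_train_success_soc", 1.2)
        assert out.value("prop_train_success_soc") == 1.0

    def test_unknown_name_rejected(self, fixture_ps):
        with pytest.raises(ParameterError, match="nonexistent"):
            perturb(fixture_ps, "nonexistent", 1.1)

    @given(st.sampled_from(["ttd", "ward_los_days", "cost_home_infection"]),
           st.floats(0.5, 2.0))
    def test_perturb_inverse_recovers(self, name, factor):
        ps = default_fixture()
        back = perturb(perturb(ps, name, factor), name, 1.0 / factor)
        assert back.value(name) == pytest.approx(ps.value(name), rel=1e-9)

    def test_sample_deterministic_per_seed(self, fixture_ps):
        a, b = sample(fixture_ps, 42), sample(fixture_ps, 42)
        assert all(a.value(n) == b.value(n) for n in fixture_ps.names())
        c = sample(fixture_ps, 43)
        assert any(a.value(n) != c.value(n) for n in fixture_ps.names())

    def test_degenerate_sample_equals_base(self, fixture_ps):
        frozen = fixture_ps.model_copy(
            update={
                "parameters": {
                    n: p.model_copy(update={"uncertainty_frac": 0.0})
                    for n, p in fixture_ps.parameters.items()
                }
            }
        )
        drawn = sample(frozen, 1)
        assert all(drawn.value(n) == fixture_ps.value(n) for n in fixture_ps.names())

    def test_sampled_cost_mean_matches_base(self, fixture_ps):
        rng = np.random.default_rng(5)
        base = fixture_ps.value("cost_rehospitalization")
        draws = np.array(
            [sample(fixture_ps, rng).value("cost_rehospitalization") for _ in range(800)]
        )
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - base) < 4 * se


class TestSerialization:
    def test_yaml_roundtrip_bit_exact(self, fixture_ps):
        again = load_parameters(dump_parameters(fixture_ps))
        assert again.content_hash() == fixture_ps.content_hash()

    def test_frame_export_covers_registry(self, fixture_ps):
        df = fixture_ps.to_frame()
        assert set(df["name"]) == set(fixture_ps.names())
        assert (df["uncertainty_frac"] >= 0).all()

    def test_schema_description_mentions_parameters(self, fixture_ps):
        schema = fixture_ps.schema_description()
        assert "parameters" in schema["properties"]
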
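"""Exposure model: curve interpolation, coefficient lookup, multiplicative form."""

import datetime as dt
import math

import pytest
from hypothesis import given, settings, strategies as st

from expotra import (
    CoefficientTable,
    ConfigurationError,
    ExposureScenario,
    InitialExposureCurve,
    Substance,
    default_baseline_config,
    default_config,
    ecetoc_tra_baseline,
    initial_exposure,
    load_configs,
    lookup_coefficients,
    modelled_exposure,
    save_configs,
)

ETHANOL = Substance("64-17-5", "ethanol", 59.0, 46.07)
BENZENE = Substance("71-43-2", "benzene", 127.0, 78.11)


def make_substance(vp):
    return Substance("7732-18-5", "probe", vp, 100.0)


def make_scenario(substance=None, operation="weighing_mixing", duration=30.0,
                  fraction=100.0, lev=False, rpe=False, sid="s1"):
    return ExposureScenario(
        scenario_id=sid, operator_id="OP1", date=dt.date(2015, 6, 1),
        substance=substance if substance is not None else make_substance(20.0),
        operation=operation, duration=duration, fraction=fraction,
        lev_present=lev, rpe_worn=rpe,
    )


def loglinear_oracle(vp, anchors):
    """Independent piecewise interpolation: linear in ln(vp), clamped."""
    if vp <= anchors[0][0]:
        return anchors[0][1]
    if vp >= anchors[-1][0]:
        return anchors[-1][1]
    for (va, ea), (vb, eb) in zip(anchors, anchors[1:]):
        if va <= vp <= vb:
            w = (math.log(vp) - math.log(va)) / (math.log(vb) - math.log(va))
            return (1 - w) * ea + w * eb


class TestInitialExposureCurve:
    def test_ethanol_override_is_200_ppm(self, config):
        assert initial_exposure(ETHANOL, config.curve) == 200.0

    def test_value_at_anchor_is_anchor_ordinate(self, config):
        for vp, ppm in config.curve.anchors:
            assert initial_exposure(make_substance(vp), config.curve) == ppm

    def test_geometric_midpoint_matches_interpolation_oracle(self, config):
        anchors = config.curve.anchors
        for (va, _), (vb, _) in zip(anchors, anchors[1:]):
            vp = math.sqrt(va * vb)
            got = initial_exposure(make_substance(vp), config.curve)
            assert got == pytest.approx(loglinear_oracle(vp, anchors), rel=1e-12)

    @given(vp=st.floats(1e-3, 1e4))
    @settings(max_examples=150, derandomize=True)
    def test_interpolation_matches_oracle_everywhere(self, vp):
        curve = default_config().curve
        got = initial_exposure(make_substance(vp), curve)
        assert got == pytest.approx(loglinear_oracle(vp, curve.anchors), rel=1e-12)

    def test_clamping_outside_anchor_range(self, config):
        lo = initial_exposure(make_substance(1e-6), config.curve)
        hi = initial_exposure(make_substance(1e6), config.curve)
        assert lo == config.curve.anchors[0][1]
        assert hi == config.curve.anchors[-1][1]

    def test_invalid_curves_rejected(self):
        with pytest.raises(ConfigurationError):
            InitialExposureCurve(anchors=())
        with pytest.raises(ConfigurationError):
            InitialExposureCurve(anchors=((5.0, 10.0), (5.0, 20.0)))
        with pytest.raises(ConfigurationError):
            InitialExposureCurve(anchors=((1.0, 50.0), (10.0, 10.0)))

    def test_missing_vapor_pressure_names_substance(self, config):
        ghost = Substance("7732-18-5", "ghost", None, 100.0)
        with pytest.raises(ValueError, match="ghost"):
            initial_exposure(ghost, config.curve)


class TestCoefficients:
    def test_mask_coefficient_is_0_001(self, config):
        *_, d = lookup_coefficients(make_scenario(rpe=True), config.coefficients)
        assert d == 0.001

    def test_benzene_lev_coefficient_is_0_03(self, config):
        _, _, c, _ = lookup_coefficients(
            make_scenario(substance=BENZENE, lev=True), config.coefficients
        )
        assert c == 0.03

    def test_no_protection_top_bands_gives_all_ones(self, config):
        coeffs = lookup_coefficients(
            make_scenario(duration=480.0, fraction=100.0), config.coefficients
        )
        assert coeffs == (1.0, 1.0, 1.0, 1.0)

    def test_band_upper_bound_takes_that_band(self, config):
        a15, *_ = lookup_coefficients(
            make_scenario(duration=15.0), config.coefficients
        )
        a16, *_ = lookup_coefficients(
            make_scenario(duration=15.001), config.coefficients
        )
        assert a15 == 0.1 and a16 == 0.2

    def test_ethanol_uses_its_own_duration_table(self, config):
        table = CoefficientTable(
            duration_bands=config.coefficients.duration_bands,
            ethanol_duration_bands=((60.0, 0.5), (math.inf, 1.0)),
            fraction_bands=config.coefficients.fraction_bands,
            lev_factor=0.1, rpe_factor=0.001,
        )
        a_eth, *_ = lookup_coefficients(
            make_scenario(substance=ETHANOL, duration=30.0), table
        )
        a_std, *_ = lookup_coefficients(make_scenario(duration=30.0), table)
        assert (a_eth, a_std) == (0.5, 0.2)

    def test_value_above_all_bands_warns_and_uses_one(self, caplog):
        table = CoefficientTable(
            duration_bands=((15.0, 0.5), (240.0, 1.0)),
            fraction_bands=((100.0, 1.0),),
            lev_factor=0.1, rpe_factor=0.1,
        )
        with caplog.at_level("WARNING", logger="expotra.model"):
            a, *_ = lookup_coefficients(make_scenario(duration=300.0), table)
        assert a == 1.0
        assert "above all configured bands" in caplog.text

    def test_invalid_tables_rejected(self):
        with pytest.raises(ConfigurationError):
            CoefficientTable(duration_bands=((15.0, 0.0), (math.inf, 1.0)),
                             fraction_bands=((math.inf, 1.0),),
                             lev_factor=0.1, rpe_factor=0.1)
        with pytest.raises(ConfigurationError):
            CoefficientTable(duration_bands=((15.0, 0.6), (60.0, 0.2),
                                             (math.inf, 1.0)),
                             fraction_bands=((math.inf, 1.0),),
                             lev_factor=0.1, rpe_factor=0.1)
        with pytest.raises(ConfigurationError):
            CoefficientTable(duration_bands=((math.inf, 1.0),),
                             fraction_bands=((math.inf, 1.0),),
                             lev_factor=1.5, rpe_factor=0.1)


scenario_strategy = st.builds(
    make_scenario,
    substance=st.sampled_from(
        [ETHANOL, BENZENE, make_substance(0.5), make_substance(20.0),
         make_substance(400.0)]
    ),
    duration=st.floats(1.0, 480.0),
    fraction=st.floats(0.01, 100.0),
    lev=st.booleans(),
    rpe=st.booleans(),
)


class TestModelledExposure:
    def test_all_unit_coefficients_reproduce_initial(self, config):
        est = modelled_exposure(
            make_scenario(duration=480.0, fraction=100.0), config
        )
        assert est.modelled_exposure == est.initial_exposure

    def test_hand_product_ethanol_with_mask(self, config):
        # 200 ppm x A(30 min)=0.2 x 1 x 1 x D=0.001 -> 0.04 ppm
        est = modelled_exposure(
            make_scenario(substance=ETHANOL, duration=30.0, rpe=True), config
        )
        assert est.initial_exposure == 200.0
        assert est.modelled_exposure == pytest.approx(0.04, rel=1e-12)

    def test_ethanol_initial_term_ignores_curve_anchors(self, config):
        distorted = InitialExposureCurve(
            anchors=((0.1, 1.0), (1000.0, 1.0)),
            overrides=dict(config.curve.overrides),
        )
        cfg = default_config()
        cfg = type(cfg)(curve=distorted, coefficients=cfg.coefficients,
                        tag=cfg.tag)
        est = modelled_exposure(make_scenario(substance=ETHANOL), cfg)
        assert est.initial_exposure == 200.0

    @given(scenario=scenario_strategy)
    @settings(max_examples=150, derandomize=True)
    def test_factorization_and_bounds(self, scenario):
        est = modelled_exposure(scenario, default_config())
        product = (est.initial_exposure * est.coeff_a * est.coeff_b
                   * est.coeff_c * est.coeff_d)
        assert est.modelled_exposure == pytest.approx(product, rel=1e-12)
        assert 0.0 <= est.modelled_exposure <= est.initial_exposure
        for c in (est.coeff_a, est.coeff_b, est.coeff_c, est.coeff_d):
            assert 0.0 < c <= 1.0

    @given(
        vp=st.floats(0.01, 1000.0), factor=st.floats(1.01, 10.0),
        duration=st.floats(1.0, 400.0), extra_minutes=st.floats(0.1, 200.0),
        fraction=st.floats(0.1, 99.0), extra_fraction=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity_in_drivers_and_protection(
        self, vp, factor, duration, extra_minutes, fraction, extra_fraction
    ):
        cfg = default_config()

        def run(**kw):
            return modelled_exposure(make_scenario(**kw), cfg).modelled_exposure

        base = dict(substance=make_substance(vp), duration=duration,
                    fraction=fraction)
        assert run(**{**base, "substance": make_substance(vp * factor)}) >= run(**base)
        assert run(**{**base, "duration": duration + extra_minutes}) >= run(**base)
        assert run(**{**base, "fraction": min(100.0, fraction * (1 + extra_fraction))}) >= run(**base)
        assert run(**{**base, "lev": True}) <= run(**base)
        assert run(**{**base, "rpe": True}) <= run(**base)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            make_scenario(duration=0.0)
        with pytest.raises(ValueError):
            make_scenario(fraction=101.0)
        with pytest.raises(ValueError):
            make_scenario(operation="distilling")


class TestBaselineAndConfigIO:
    def test_baseline_has_no_special_cases(self, baseline_config):
        est = ecetoc_tra_baseline(
            make_scenario(substance=ETHANOL, duration=30.0), baseline_config
        )
        assert est.model_tag == "ecetoc_tra_v3"
        assert est.initial_exposure != 200.0
        _, _, c, _ = lookup_coefficients(
            make_scenario(substance=BENZENE, lev=True),
            baseline_config.coefficients,
        )
        assert c == baseline_config.coefficients.lev_factor

    def test_baseline_band_walk_matches_hand_lookup(self, baseline_config):
        # vp 20 mbar sits on the (20, 50) anchor; 30 min -> 0.2; 5% -> 0.2;
        # LEV -> 0.1; mask -> 0.1: 50 x 0.2 x 0.2 x 0.1 x 0.1 = 0.02 ppm
        est = ecetoc_tra_baseline(
            make_scenario(duration=30.0, fraction=5.0, lev=True, rpe=True),
            baseline_config,
        )
        assert est.modelled_exposure == pytest.approx(0.02, rel=1e-12)

    def test_same_scenario_differs_only_via_config(self, config, baseline_config):
        sc = make_scenario(substance=ETHANOL, duration=30.0, rpe=True)
        proposed = modelled_exposure(sc, config)
        baseline = modelled_exposure(sc, baseline_config)
        assert proposed.scenario_id == baseline.scenario_id
        assert proposed.model_tag != baseline.model_tag
        assert proposed.modelled_exposure != baseline.modelled_exposure

    def test_config_round_trip_reproduces_estimates(self, tmp_path, config,
                                                    baseline_config):
        path = tmp_path / "models.yaml"
        save_configs(path, {config.tag: config,
                            baseline_config.tag: baseline_config})
        reloaded = load_configs(path)
        scenarios = [
            make_scenario(substance=ETHANOL, duration=30.0, rpe=True, sid="a"),
            make_scenario(substance=BENZENE, lev=True, sid="b"),
            make_scenario(duration=100.0, fraction=3.0, sid="c"),
        ]
        for tag, cfg in ((config.tag, config),
                         (baseline_config.tag, baseline_config)):
            for sc in scenarios:
                assert (modelled_exposure(sc, reloaded[tag])
                        == modelled_exposure(sc, cfg))
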
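"""Rate laws, domain types and ODE assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txflow import (
    GeneConstruct,
    NetworkSpec,
    build_ode_system,
    constant_protocol,
    hill_repression,
    reference_parameters,
    simulate,
    steady_state_mrna_ratio,
    transcription_rate,
)
from txflow.circuit_model import ConfigurationError, UncharacterizedPartError

from conftest import cascade_steady_state

LAMBDA = 0.40 / 22.5  # default chemostat dilution rate, 1/min


class TestHillRepression:
    @pytest.mark.parametrize(
        "conc, kd, n, expected",
        [
            (0.0, 5.0, 2.0, 1.0),  # no repressor, full expression
            (5.0, 5.0, 1.0, 0.5),  # half-repression at the dissociation constant
            (5.0, 5.0, 3.7, 0.5),
            (10.0, 5.0, 2.0, 0.2),  # 1/(1 + 2^2)
        ],
    )
    def test_reference_values(self, conc, kd, n, expected):
        assert hill_repression(conc, kd, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1.0, 5.0, 2.0), (1.0, 0.0, 2.0), (1.0, -2.0, 2.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            hill_repression(*bad)

    @given(
        kd=st.floats(0.1, 1e3),
        n=st.floats(1.0, 4.0),
        r1=st.floats(0.0, 1e4),
        r2=st.floats(0.0, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing(self, kd, n, r1, r2):
        lo, hi = sorted((r1, r2))
        assert hill_repression(hi, kd, n) <= hill_repression(lo, kd, n) <= 1.0


class TestTranscriptionRate:
    def test_constitutive_rate_linear_in_template(self, db_params):
        g = GeneConstruct(name="g", promoter="p70a", orf="deGFP", riboj=True)
        # reference transcription rate of the constitutive promoter: 0.5/min/nM
        assert transcription_rate(g, 1.0, 0.0, 0.0, db_params) == pytest.approx(0.5)
        assert transcription_rate(g, 3.0, 0.0, 0.0, db_params) == pytest.approx(1.5)

    def test_inducible_requires_activator(self, db_params):
        g = GeneConstruct(name="g", promoter="p19a", orf="deGFP", riboj=True)
        assert transcription_rate(g, 10.0, 0.0, 0.0, db_params) == 0.0

    def test_saturated_activation_with_half_repression(self, db_params):
        g = GeneConstruct(
            name="g", promoter="p19a", orf="deGFP", operator="TetRO1", riboj=True
        )
        sigma_huge = 1e9
        rate = transcription_rate(g, 2.0, sigma_huge, db_params.kd_rep["TetR"], db_params)
        assert rate == pytest.approx(db_params.kcat_tx_s19 * 2.0 * 0.5, rel=1e-6)

    def test_negative_concentration_rejected(self, db_params):
        g = GeneConstruct(name="g", promoter="p70a", orf="deGFP", riboj=True)
        with pytest.raises(ValueError):
            transcription_rate(g, -1.0, 0.0, 0.0, db_params)


class TestSteadyStateRatio:
    def test_reference_operating_point(self, db_params):
        """kcat 0.5, kdeg 0.04, lambda = 0.4/22.5 gives a ratio of ~8.65."""
        g = GeneConstruct(name="g", promoter="p70a", orf="TetR", riboj=True)
        p = db_params.copy()
        p.kcat_tx_s70 = 0.5
        p.kdeg_mrna["TetR"] = 0.04
        ratio = steady_state_mrna_ratio(g, p, LAMBDA)
        assert ratio == pytest.approx(0.5 / (0.04 + LAMBDA), rel=1e-12)
        assert ratio == pytest.approx(8.653, abs=0.005)
        assert 2.0 < ratio < 500.0

    def test_vanishing_transcription_gives_zero_ratio(self, db_params):
        g = GeneConstruct(name="g", promoter="p70a", orf="TetR", riboj=True)
        p = db_params.copy()
        p.kcat_tx_s70 = 1e-12
        assert steady_state_mrna_ratio(g, p, LAMBDA) < 1e-9

    def test_degenerate_denominator_flagged(self, db_params):
        g = GeneConstruct(name="g", promoter="p70a", orf="TetR", riboj=True)
        p = db_params.copy()
        p.kdeg_mrna["TetR"] = 0.0
        assert math.isinf(steady_state_mrna_ratio(g, p, 0.0))

    def test_negative_dilution_rejected(self, db_params):
        g = GeneConstruct(name="g", promoter="p70a", orf="TetR", riboj=True)
        with pytest.raises(ValueError):
            steady_state_mrna_ratio(g, db_params, -0.1)


class TestODEAssembly:
    def test_zero_state_zero_inflow_is_fixed_point(self, one_gene_network, db_params):
        system = build_ode_system(one_gene_network, db_params)
        dy = system.rhs(0.0, np.zeros(system.n_states), np.zeros(1), LAMBDA)
        assert np.all(dy == 0.0)

    def test_steady_state_matches_closed_form(self, one_gene_network, db_params, one_gene_protocol):
        """Numerical plateau of the constitutive cascade agrees with the
        analytic steady state to 1e-6 relative."""
        system = build_ode_system(one_gene_network, db_params)
        traj = simulate(system, one_gene_protocol, rtol=1e-10, atol=1e-12)
        ss = cascade_steady_state(db_params, 1.0, LAMBDA)
        assert traj.state("DNA_g")[-1] == pytest.approx(ss["DNA"], rel=1e-6)
        assert traj.state("mRNA_g")[-1] == pytest.approx(ss["mRNA"], rel=1e-6)
        assert traj.observable("Pmat_g")[-1] == pytest.approx(ss["mature"], rel=1e-6)

    def test_linearity_in_template_dose(self, one_gene_network, db_params):
        """With no regulation, doubling the inflow doubles steady-state levels."""
        system = build_ode_system(one_gene_network, db_params)
        out = []
        for f in (0.1, 0.2):
            protocol = constant_protocol(["g"], {"g": 5.0}, {"g": f}, 48)
            traj = simulate(system, protocol)
            out.append((traj.state("mRNA_g")[-1], traj.observable("Pmat_g")[-1]))
        assert out[1][0] == pytest.approx(2 * out[0][0], rel=1e-5)
        assert out[1][1] == pytest.approx(2 * out[0][1], rel=1e-5)

    def test_non_negativity_under_random_protocols(self, db_params):
        from txflow import make_iffl
        from txflow.chemostat_io import InflowProtocol

        net = make_iffl("CymR", riboj=False)
        system = build_ode_system(net, db_params)
        rng = np.random.default_rng(5)
        names = tuple(c.name for c in net.constructs)
        for _ in range(3):
            frac = rng.uniform(0, 0.33, size=(10, 3))
            protocol = InflowProtocol(
                constructs=names, stocks={n: 5.0 for n in names}, fractions=frac
            )
            traj = simulate(system, protocol)
            assert np.all(traj.states >= 0.0)
            assert np.all(np.isfinite(traj.states))

    def test_missing_translation_rate_is_explicit(self):
        """A part with no characterized translation rate raises the
        uncharacterized-part error that drives RiboJ-factor extrapolation."""
        from txflow import make_bistable_switch

        step_params, _ = reference_parameters("step")  # no mmCherry entries
        with pytest.raises(UncharacterizedPartError, match="mmCherry"):
            build_ode_system(make_bistable_switch(), step_params)


class TestDomainTypes:
    def test_unknown_enums_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneConstruct(name="x", promoter="p15a", orf="deGFP")
        with pytest.raises(ConfigurationError):
            GeneConstruct(name="x", promoter="p70a", orf="GFPmut3")
        with pytest.raises(ConfigurationError):
            GeneConstruct(name="x", promoter="p19a", orf="deGFP", operator="LacO")

    def test_duplicate_construct_names_rejected(self):
        g = GeneConstruct(name="g", promoter="p70a", orf="deGFP", riboj=True)
        with pytest.raises(ConfigurationError):
            NetworkSpec(constructs=(g, g))

    def test_network_yaml_round_trip(self):
        from txflow import make_pulse_decoder

        net = make_pulse_decoder()
        again = NetworkSpec.from_yaml(net.to_yaml())
        assert again == net
        assert again.species == net.species

    def test_parameter_label_round_trip(self, db_params):
        p = db_params.copy()
        for lbl in p.labels():
            v = p[lbl]
            p[lbl] = v * 2
            assert p[lbl] == v * 2
            p[lbl] = v

    def test_parameter_json_round_trip(self, db_params):
        from txflow.circuit_model import ParameterSet

        again = ParameterSet.from_json_dict(db_params.to_json_dict())
        assert again.labels() == db_params.labels()
        for lbl in db_params.labels():
            assert again[lbl] == db_params[lbl]
        assert again.kmat == db_params.kmat

    def test_validate_enforces_positivity_and_hill_range(self, db_params):
        p = db_params.copy()
        p.n_rep["TetR"] = 5.0
        with pytest.raises(ConfigurationError):
            p.validate()
        q = db_params.copy()
        q.kcat_tx_s70 = -1.0
        with pytest.raises(ConfigurationError):
            q.validate()

    def test_category_mapping(self, db_params):
        from txflow.circuit_model import ParameterSet

        cats = {ParameterSet.category_of(l) for l in db_params.labels()}
        assert cats == {"K_TX", "K_TL", "K_reg", "K_deg"}
        assert ParameterSet.category_of("kd_s19") == "K_TX"
        assert ParameterSet.category_of("n_rep.PhlF") == "K_reg"
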
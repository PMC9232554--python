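"""Database objective, soft constraints, ensemble fitting and summaries."""

import numpy as np
import pytest

from txflow import (
    Experiment,
    ExperimentDatabase,
    GeneConstruct,
    NetworkSpec,
    build_ode_system,
    constant_protocol,
    distribution_width,
    fit_database,
    objective,
    prediction_band,
    riboj_factor,
    sample_parameter_sets,
    simulate,
    soft_constraint_penalty,
)
from txflow.fitting import FittingError, ParameterEnsemble

LAMBDA = 0.40 / 22.5


def one_gene_database(params, n_cycles=8, noise=None, seed=0):
    net = NetworkSpec(
        constructs=(GeneConstruct(name="g", promoter="p70a", orf="deGFP", riboj=True),),
        name="one-gene",
    )
    protocol = constant_protocol(["g"], {"g": 5.0}, {"g": 0.2}, n_cycles)
    traj = simulate(build_ode_system(net, params), protocol, rtol=1e-8)
    observed = traj.observables.copy()
    if noise:
        rng = np.random.default_rng(seed)
        observed = np.clip(observed + rng.normal(0, noise, observed.shape), 0, None)
    exp = Experiment(
        network=net,
        protocol=protocol,
        times=traj.times,
        observed=observed,
        reporters=traj.observable_species,
        name="one-gene-step",
    )
    return ExperimentDatabase(experiments=[exp])


class TestSoftConstraint:
    def _params_with_ratio(self, db_params, ratio):
        p = db_params.copy()
        p.kcat_tx_s70 = ratio * (p.kdeg_mrna["deGFP"] + LAMBDA)
        return p

    def _net(self):
        return NetworkSpec(
            constructs=(GeneConstruct(name="g", promoter="p70a", orf="deGFP", riboj=True),),
            name="one-gene",
        )

    @pytest.mark.parametrize("ratio", [2.0, 2.5, 8.653, 499.0, 500.0])
    def test_accepted_ratios_have_zero_penalty(self, db_params, ratio):
        p = self._params_with_ratio(db_params, ratio)
        assert soft_constraint_penalty(p, [self._net()], LAMBDA) == 0.0

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 1.999, 501.0, 900.0])
    def test_rejected_ratios_have_positive_penalty(self, db_params, ratio):
        p = self._params_with_ratio(db_params, ratio)
        assert soft_constraint_penalty(p, [self._net()], LAMBDA) > 0.0

    def test_penalty_grows_with_violation(self, db_params):
        pens = [
            soft_constraint_penalty(self._params_with_ratio(db_params, r), [self._net()], LAMBDA)
            for r in (1.5, 1.0, 0.5)
        ]
        assert pens[0] < pens[1] < pens[2]


class TestObjective:
    def test_zero_at_truth_on_noiseless_data(self, db_params):
        db = one_gene_database(db_params)
        assert objective(db, db_params, rtol=1e-8) < 1e-8

    def test_perturbations_increase_objective(self, db_params):
        db = one_gene_database(db_params)
        base = objective(db, db_params, rtol=1e-8)
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = db_params.copy()
            lbl = rng.choice(["kcat_tx_s70", "kcat_tl.deGFP.riboj", "kdeg_mrna.deGFP"])
            p[lbl] = p[lbl] * float(rng.uniform(1.2, 2.0))
            assert objective(db, p, rtol=1e-8) > base

    def test_riboj_specific_rate_only_touches_riboj_experiments(self, db_params):
        """Changing a RiboJ-specific translation rate leaves the residuals of
        the uninsulated variant untouched -- the structural isolation that
        makes variant pairs informative."""
        from txflow import make_iffl
        from txflow.circuit_library import characterization_protocol, iffl_characterization_registry

        reg = iffl_characterization_registry()
        dbs = {}
        for riboj in (True, False):
            entry = next(
                e for e in reg.entries
                if e.model_id == f"IFFL-TetR{'-RiboJ' if riboj else ''}" and e.kind == "step"
            )
            protocol = characterization_protocol(entry, n_cycles=6)
            traj = simulate(build_ode_system(entry.network, db_params), protocol, rtol=1e-8)
            dbs[riboj] = ExperimentDatabase(experiments=[Experiment(
                network=entry.network, protocol=protocol, times=traj.times,
                observed=traj.observables, reporters=traj.observable_species,
            )])
        p = db_params.copy()
        p.kcat_tl[("TetR", True)] *= 1.5
        assert objective(dbs[True], p, rtol=1e-8) > 1e-6
        assert objective(dbs[False], p, rtol=1e-8) < 1e-10

    def test_shared_transcription_rate_touches_every_experiment(self, db_params):
        from txflow import make_iffl
        from txflow.circuit_library import characterization_protocol, iffl_characterization_registry

        reg = iffl_characterization_registry()
        p = db_params.copy()
        p.kcat_tx_s19 *= 1.3
        for entry in reg.entries[:4]:
            protocol = characterization_protocol(entry, n_cycles=6)
            traj = simulate(build_ode_system(entry.network, db_params), protocol, rtol=1e-8)
            db = ExperimentDatabase(experiments=[Experiment(
                network=entry.network, protocol=protocol, times=traj.times,
                observed=traj.observables, reporters=traj.observable_species,
            )])
            assert objective(db, p, rtol=1e-8) > 1e-6


class TestDistributionSummaries:
    def test_width_of_one_to_ten(self):
        assert distribution_width(list(range(1, 11))) == pytest.approx(8.0 / 3.0)

    def test_constant_distribution_width_is_one(self):
        assert distribution_width([3.7] * 12) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 9, size=25)
        assert distribution_width(vals * 13.0) == pytest.approx(distribution_width(vals))

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError):
            distribution_width([1.0] * 9)

    @pytest.mark.parametrize("pairs, expected", [
        ([(2.0, 1.0), (3.0, 1.0), (1.0, 1.0)], 2.0),
        ([(5.0, 2.0)], 2.5),
    ])
    def test_riboj_factor_median(self, pairs, expected):
        assert riboj_factor(pairs) == pytest.approx(expected)

    def test_riboj_factor_round_trip(self):
        f = riboj_factor([(3.0, 1.5)])
        rate = 0.8
        assert rate * f / f == pytest.approx(rate, abs=1e-12)

    def test_riboj_factor_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            riboj_factor([(1.0, 0.0)])


class TestSampling:
    def test_samples_respect_bounds_and_hill_linearity(self, db_params, db_bounds):
        rng = np.random.default_rng(1)
        sets = sample_parameter_sets(db_params, db_bounds, 50, rng)
        for p in sets:
            for lbl, (lo, hi) in db_bounds.items():
                assert lo - 1e-12 <= p[lbl] <= hi + 1e-12
        hills = np.array([p.n_rep["TetR"] for p in sets])
        assert hills.min() < 1.7 and hills.max() > 3.0  # spans the box linearly


class TestFitDatabase:
    def test_recovers_rate_product_on_noiseless_single_gene(self, db_params, db_bounds):
        """kcat_TX * kcat_TL is identifiable from a single gene even when the
        factors are individually covariant."""
        db = one_gene_database(db_params, n_cycles=8)
        bounds = {k: db_bounds[k] for k in ("kcat_tx_s70", "kcat_tl.deGFP.riboj", "kdeg_mrna.deGFP")}
        ens = fit_database(db, db_params, bounds, n_agents=20, n_rounds=15, seed=4)
        best = ens.best
        truth = db_params.kcat_tx_s70 * db_params.kcat_tl[("deGFP", True)]
        got = best.kcat_tx_s70 * best.kcat_tl[("deGFP", True)]
        assert got == pytest.approx(truth, rel=0.10)
        assert ens.best_score < 1e-2

    def test_collapsed_bounds_give_identical_members_width_one(self, db_params):
        db = one_gene_database(db_params)
        point = {
            "kcat_tx_s70": (db_params.kcat_tx_s70, db_params.kcat_tx_s70),
            "kcat_tl.deGFP.riboj": (db_params.kcat_tl[("deGFP", True)],) * 2,
        }
        ens = fit_database(db, db_params, point, n_agents=20, n_rounds=2, seed=0)
        assert len(ens) >= 10
        assert distribution_width(ens, "kcat_tx_s70") == pytest.approx(1.0)

    def test_agent_floor_enforced(self, db_params, db_bounds):
        db = one_gene_database(db_params)
        with pytest.raises(ValueError):
            fit_database(db, db_params, db_bounds, n_agents=10, n_rounds=1, seed=0)

    def test_no_free_parameters_is_an_error(self, db_params):
        db = one_gene_database(db_params)
        with pytest.raises(FittingError):
            fit_database(db, db_params, {"kd_rep.PhlF": (1.0, 2.0)}, n_agents=20, n_rounds=1, seed=0)


class TestPredictionBand:
    def test_identical_members_have_zero_sd(self, db_params, one_gene_network):
        protocol = constant_protocol(["g"], {"g": 5.0}, {"g": 0.2}, 6)
        ens = ParameterEnsemble(members=[(db_params.copy(), 0.0) for _ in range(4)])
        times, mean, sd, reporters = prediction_band(ens, one_gene_network, protocol, quantile=1.0)
        assert np.all(sd == 0.0)
        assert reporters == ("Pmat_g",)

    def test_band_mean_lies_within_member_envelope(self, db_params, one_gene_network):
        protocol = constant_protocol(["g"], {"g": 5.0}, {"g": 0.2}, 6)
        members = []
        for f in (0.8, 1.0, 1.25):
            p = db_params.copy()
            p.kcat_tl[("deGFP", True)] *= f
            members.append((p, 0.0))
        ens = ParameterEnsemble(members=members)
        times, mean, sd, _ = prediction_band(ens, one_gene_network, protocol, quantile=1.0)
        sims = [
            simulate(build_ode_system(one_gene_network, p), protocol, rtol=1e-6).observables
            for p, _ in ens.members
        ]
        lo = np.min(sims, axis=0)
        hi = np.max(sims, axis=0)
        assert np.all(mean >= lo - 1e-12) and np.all(mean <= hi + 1e-12)

    def test_empty_quantile_rejected(self, db_params, one_gene_network):
        ens = ParameterEnsemble(members=[(db_params, 0.0)])
        protocol = constant_protocol(["g"], {"g": 5.0}, {"g": 0.2}, 4)
        with pytest.raises(ValueError):
            prediction_band(ens, one_gene_network, protocol, quantile=0.0)
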
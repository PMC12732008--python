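"""Adversarial twin generator: determinism, conditioning soundness, DAG
compliance, convergence criterion and domain closure."""

import numpy as np
import pandas as pd
import pytest

from usvtwin import gan
from usvtwin.cohort import Cohort
from usvtwin.source import reference_count_cohort

FAST = gan.GANConfig(epochs=120, seed=0)


@pytest.fixture(scope="module")
def fast_model(reference_cohort):
    """A briefly trained model — enough for structural/contract checks."""
    return gan.train_cgan(reference_cohort, config=FAST)


class TestDagSpec:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            gan.DAGSpec(("a", "b"), (("a", "b"), ("b", "a")), ())

    def test_terminal_outcome_with_outgoing_edge_rejected(self):
        with pytest.raises(ValueError, match="outgoing"):
            gan.DAGSpec(("a", "b"), (("a", "b"),), ("a",))

    def test_default_dag_terminals(self):
        dag = gan.default_dag()
        assert set(dag.terminal_outcomes) == {"recanalization", "recurrence", "major_bleed"}
        for node in dag.terminal_outcomes:
            assert set(dag.parents(node)) == set(gan.DEFAULT_CONDITIONING)


class TestCheckConvergence:
    def test_constant_losses_converged(self):
        history = {"generator": [0.7] * 200, "discriminator": [0.69] * 200}
        assert gan.check_convergence(history, window=100, tol=0.05)

    def test_doubling_loss_not_converged(self):
        diverging = [0.1 * 2**i for i in range(120)]
        history = {"generator": [0.7] * 120, "discriminator": diverging}
        assert not gan.check_convergence(history, window=100, tol=0.05)

    def test_small_sinusoid_converged(self):
        t = np.arange(300)
        mean, tol = 1.0, 0.05
        wave = mean + 0.5 * tol * mean * np.sin(t / 7.0)
        assert gan.check_convergence({"g": wave.tolist(), "d": wave.tolist()}, 100, tol)

    def test_short_history_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            gan.check_convergence({"g": [0.7] * 10}, window=100, tol=0.05)


class TestTraining:
    def test_same_seed_gives_identical_loss_histories(self, reference_cohort):
        m1 = gan.train_cgan(reference_cohort, config=FAST)
        m2 = gan.train_cgan(reference_cohort, config=FAST)
        assert m1.loss_history == m2.loss_history

    def test_empty_cohort_rejected(self, reference_cohort):
        empty = Cohort(reference_cohort.df.iloc[0:0], list(reference_cohort.schema))
        with pytest.raises(ValueError, match="empty"):
            gan.train_cgan(empty, config=FAST)

    def test_conditioning_on_outcome_rejected_at_config(self, reference_cohort):
        cfg = gan.GANConfig(
            epochs=10, conditioning_vars=("age", "recurrence"), seed=0
        )
        with pytest.raises(ValueError, match="terminal outcomes"):
            gan.train_cgan(reference_cohort, config=cfg)

    def test_degenerate_cohort_collapses_to_the_single_record(self):
        base = reference_count_cohort().df.iloc[[3]]
        df = pd.concat([base] * 30, ignore_index=True)
        model = gan.train_cgan(Cohort(df), config=gan.GANConfig(epochs=800, seed=0))
        twins = gan.generate_twins(model, 30)
        for var in ("sex", "usvt_site", "treatment", "recurrence", "major_bleed", "death"):
            assert (twins.df[var] == base[var].iloc[0]).all(), var


class TestDagCompliance:
    def test_heads_see_only_ancestors_or_conditioning(self, fast_model):
        """Structural check on the network wiring: a DAG node's generator
        context is exactly its parents; other variables see only the
        conditioning covariates."""
        dag = fast_model.dag
        conditioning = set(fast_model.config.conditioning_vars)
        for name, context in fast_model.context_map.items():
            if name in dag.nodes:
                assert set(context) == set(dag.parents(name))
                assert set(context) <= dag.ancestors(name)
            else:
                assert set(context) == conditioning

    def test_custom_dag_chain_generates_in_topological_order(self, reference_cohort):
        dag = gan.DAGSpec(
            ("age", "treatment", "active_cancer", "death", "recurrence"),
            (("age", "active_cancer"), ("active_cancer", "death"), ("treatment", "recurrence")),
            ("death", "recurrence"),
        )
        cfg = gan.GANConfig(epochs=10, conditioning_vars=("age", "treatment"), seed=0)
        model = gan.train_cgan(reference_cohort, dag, cfg)
        order = [gv.name for gv in model.gen_vars]
        assert order.index("active_cancer") < order.index("death")
        assert model.context_map["death"] == ("active_cancer",)


class TestGeneration:
    def test_one_to_one_twin_size_and_schema(self, fast_model, reference_cohort):
        twins = gan.generate_twins(fast_model, 90)
        assert len(twins) == 90
        assert [s.name for s in twins.schema] == [s.name for s in reference_cohort.schema]

    def test_conditions_are_hard_constraints(self, fast_model):
        twins = gan.generate_twins(fast_model, 60, conditions={"treatment": "DOAC"})
        assert (twins.df["treatment"] == "DOAC").all()
        assert twins.df["doac_agent"].notna().all()
        assert twins.df["ttr"].isna().all()

    def test_condition_on_outcome_is_contract_error(self, fast_model):
        with pytest.raises(ValueError, match="terminal outcome"):
            gan.generate_twins(fast_model, 10, conditions={"recurrence": 1})

    def test_condition_on_nonconditioning_variable_rejected(self, fast_model):
        with pytest.raises(ValueError, match="not a conditioning variable"):
            gan.generate_twins(fast_model, 10, conditions={"hemoglobin": 12.0})

    def test_zero_twins_is_empty_cohort(self, fast_model):
        assert len(gan.generate_twins(fast_model, 0)) == 0

    def test_domain_closure_for_continuous_and_categorical(self, fast_model, reference_cohort):
        twins = gan.generate_twins(fast_model, 200, seed=5)
        slack = fast_model.config.domain_slack
        for s in reference_cohort.schema:
            if s.kind == "continuous":
                train = reference_cohort.df[s.name].dropna()
                if train.empty:
                    continue
                lo, hi = train.min(), train.max()
                margin = slack * (hi - lo)
                vals = twins.df[s.name].dropna()
                assert vals.between(lo - margin - 1e-9, hi + margin + 1e-9).all(), s.name
            elif s.kind == "categorical":
                seen = set(twins.df[s.name].dropna().unique())
                assert seen <= set(s.levels), s.name

    def test_generation_reuses_training_conditioning_rows_at_1_to_1(
        self, fast_model, reference_cohort
    ):
        twins = gan.generate_twins(fast_model, 90)
        for var in fast_model.config.conditioning_vars:
            assert (
                twins.df[var].to_numpy() == reference_cohort.df[var].to_numpy()
            ).all(), var


class TestReplicas:
    def test_single_replica_matches_direct_generation(self, reference_cohort):
        replicas = gan.replicate_twins(
            reference_cohort, config=FAST, n_replicas=1, seed_base=7
        )
        from dataclasses import replace

        model = gan.train_cgan(reference_cohort, config=replace(FAST, seed=7))
        direct = gan.generate_twins(model, len(reference_cohort))
        assert replicas[0].df.equals(direct.df)

    def test_replicas_use_distinct_seeds(self, reference_cohort):
        replicas = gan.replicate_twins(
            reference_cohort, config=FAST, n_replicas=2, seed_base=0
        )
        assert not replicas[0].df.equals(replicas[1].df)

    def test_replica_count_validated(self, reference_cohort):
        with pytest.raises(ValueError):
            gan.replicate_twins(reference_cohort, config=FAST, n_replicas=0)


def test_model_checkpoint_round_trip(fast_model, tmp_path):
    path = tmp_path / "model.bin"
    fast_model.save(path)
    back = gan.GeneratorModel.load(path)
    a = gan.generate_twins(fast_model, 30, seed=9).df
    b = gan.generate_twins(back, 30, seed=9).df
    assert a.equals(b)
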
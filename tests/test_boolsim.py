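"""Boolean-network simulation and the planted-dependency generator."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ctxnet.boolsim import (
    BooleanNetwork,
    SimulationDesign,
    cholesterol_fixture,
    generate_planted,
    sample_steady_states,
)
from ctxnet.io import DOWN, NOCHANGE, UP


class TestRuleParsing:
    def test_precedence_and_parens(self):
        net = BooleanNetwork({"a": "a", "b": "b", "c": "c",
                              "x": "a OR b AND NOT c", "y": "(a OR b) AND NOT c"})
        state = {"a": 1, "b": 0, "c": 1, "x": 0, "y": 0}
        out = net.step(state)
        assert out["x"] == 1      # OR binds loosest: a OR (b AND NOT c)
        assert out["y"] == 0

    def test_constants(self):
        net = BooleanNetwork({"x": "1", "y": "0 OR x"})
        out = net.step({"x": 0, "y": 0})
        assert out["x"] == 1 and out["y"] == 0

    def test_undeclared_node_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            BooleanNetwork({"x": "ghost"})

    def test_duplicate_rule_rejected(self):
        with pytest.raises(ValueError, match="duplicate rule"):
            BooleanNetwork.from_text("x = 1\nx = 0\n")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            BooleanNetwork({"x": "x AND"})


class TestStep:
    def setup_method(self):
        self.net = BooleanNetwork({
            "statins": "statins",
            "srebp": "srebp",
            "hmgcr": "NOT statins AND srebp",
        })

    def test_inhibition_dominates(self):
        out = self.net.step({"statins": 1, "srebp": 1, "hmgcr": 1})
        assert out["hmgcr"] == 0

    def test_fixed_point_maps_to_itself(self):
        state = {"statins": 0, "srebp": 1, "hmgcr": 1}
        assert self.net.step(state) == state

    def test_clamp_overrides_rule(self):
        clamped = self.net.with_clamps(hmgcr=0)
        out = clamped.step({"statins": 0, "srebp": 1, "hmgcr": 1})
        assert out["hmgcr"] == 0

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError, match="does not cover"):
            self.net.step({"statins": 1})


class TestAttractors:
    def test_fixed_point_detected(self):
        net = BooleanNetwork({"x": "x"})
        attractor, reached = net.attractor_from({"x": 1})
        assert reached and attractor == [{"x": 1}]

    def test_cycle_detected(self):
        net = BooleanNetwork({"x": "NOT x"})
        attractor, reached = net.attractor_from({"x": 0})
        assert reached and len(attractor) == 2

    def test_step_cap_warns_and_returns_last(self, caplog):
        net = BooleanNetwork({"a": "a", "b": "b", "x": "NOT x"})
        with caplog.at_level("WARNING"):
            attractor, reached = net.attractor_from({"a": 0, "b": 0, "x": 0}, max_steps=1)
        assert not reached and len(attractor) == 1
        assert "no attractor" in caplog.text


class TestCholesterolFixture:
    def setup_method(self):
        self.net = cholesterol_fixture()

    def test_statins_inhibits_reductase_with_not_logic(self):
        assert ("Statins", "HMG_CoA_reductase") in self.net.regulations()
        # clamp-free check: statins on forces the reductase off regardless
        state = {n: 1 for n in self.net.nodes}
        assert self.net.step(state)["HMG_CoA_reductase"] == 0

    def test_cholesterol_rule_is_or(self):
        ast = self.net.rules["Cholesterol"]
        assert ast[0] == "or"

    def test_all_other_multi_input_nodes_are_and(self):
        for node in self.net.nodes:
            if node == "Cholesterol" or len(self.net.parents_of(node)) < 2:
                continue
            kinds = {self.net.rules[node][0]}
            assert kinds <= {"and"}, node

    def test_feedback_loop_present(self):
        regs = self.net.regulations()
        assert ("Cholesterol", "SREBP_SCAP") in regs
        assert ("SREBP_SCAP", "HMG_CoA_reductase") in regs

    def test_statins_clamp_shuts_down_synthesis(self):
        """Every attractor state reached under statins has the reductase,
        mevalonate and all downstream products off (checked over a broad
        sample of initial states plus the all-on / all-off corners)."""
        arm = self.net.with_clamps(Statins=1)
        downstream = [
            "HMG_CoA_reductase", "Mevalonic_acid", "Isopentenyl_PP",
            "Geranyl_PP", "Farnesyl_PP", "Squalene", "Lanosterol",
            "Desmosterol", "Dehydrocholesterol_7", "Cholesterol",
        ]
        rng = np.random.default_rng(0)
        inits = [dict(zip(self.net.nodes, bits)) for bits in (
            [0] * len(self.net.nodes), [1] * len(self.net.nodes),
        )]
        for _ in range(200):
            inits.append({n: int(v) for n, v in
                          zip(self.net.nodes, rng.integers(0, 2, len(self.net.nodes)))})
        for init in inits:
            attractor, reached = arm.attractor_from(init)
            assert reached
            for state in attractor:
                assert all(state[n] == 0 for n in downstream)

    def test_attractor_always_reached_without_statins(self):
        arm = self.net.with_clamps(Statins=0)
        rng = np.random.default_rng(1)
        for _ in range(100):
            init = {n: int(v) for n, v in
                    zip(self.net.nodes, rng.integers(0, 2, len(self.net.nodes)))}
            _, reached = arm.attractor_from(init, max_steps=2 ** 14)
            assert reached


class TestSampleSteadyStates:
    def make(self, n=30, seed=5):
        design = SimulationDesign(
            arms={"statins_off": {"Statins": 0}, "statins_on": {"Statins": 1}},
            n_samples=n, seed=seed,
        )
        return sample_steady_states(cholesterol_fixture(), design)

    def test_shapes_and_condition_table(self):
        data, table = self.make()
        assert data.shape == (18, 60)
        assert set(table.labels) == {"statins_off", "statins_on"}
        assert len(table.samples_of("statins_on")) == 30

    def test_statins_arm_reductase_and_mevalonate_down(self):
        data, table = self.make()
        for sample in table.samples_of("statins_on"):
            assert data["HMG_CoA_reductase", sample] == DOWN
            assert data["Mevalonic_acid", sample] == DOWN

    def test_statins_arm_all_downstream_products_down(self):
        data, table = self.make()
        downstream = ["Isopentenyl_PP", "Geranyl_PP", "Farnesyl_PP", "Squalene",
                      "Lanosterol", "Desmosterol", "Dehydrocholesterol_7", "Cholesterol"]
        for sample in table.samples_of("statins_on"):
            for node in downstream:
                assert data[node, sample] == DOWN

    def test_boolean_maps_to_up_down_only(self):
        data, _ = self.make()
        assert set(np.unique(data.values)) <= {UP, DOWN}

    def test_deterministic_given_seed(self):
        a, _ = self.make(seed=9)
        b, _ = self.make(seed=9)
        assert np.array_equal(a.values, b.values)


class TestGeneratePlanted:
    def test_full_strength_no_noise_copies_exactly(self):
        data, cond, _ = generate_planted(
            5, 100, 2, [(("S1", "S2"), "C1", 1.0)], noise=0.0, seed=1
        )
        block = [data.sample_index(s) for s in cond.samples_of("C1")]
        assert np.array_equal(data.values[0, block], data.values[1, block])

    def test_zero_strength_independent_within_block(self):
        data, cond, _ = generate_planted(
            5, 2000, 2, [(("S1", "S2"), "C1", 0.0)], noise=0.0, seed=2
        )
        block = [data.sample_index(s) for s in cond.samples_of("C1")]
        table = np.zeros((3, 3))
        for a, b in zip(data.values[0, block], data.values[1, block]):
            table[a + 1, b + 1] += 1
        assert chi2_contingency(table).pvalue > 0.01

    def test_outside_block_independent(self):
        data, cond, _ = generate_planted(
            5, 2000, 2, [(("S1", "S2"), "C1", 1.0)], noise=0.0, seed=3
        )
        outside = [data.sample_index(s) for s in cond.samples_of("C2")]
        agree = np.mean(data.values[0, outside] == data.values[1, outside])
        assert abs(agree - 1 / 3) < 0.05

    def test_marginals_within_three_se(self):
        marginals = (0.2, 0.5, 0.3)
        data, _, _ = generate_planted(
            3, 1000, 2, [], noise=0.0, marginals=marginals, seed=4
        )
        n = data.values.size
        for state, p in zip((DOWN, NOCHANGE, UP), marginals):
            freq = np.mean(data.values == state)
            assert abs(freq - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_noise_flips_change_states(self):
        a, _, _ = generate_planted(5, 200, 2, [], noise=0.0, seed=5)
        b, _, _ = generate_planted(5, 200, 2, [], noise=0.3, seed=5)
        assert 0.1 < np.mean(a.values != b.values) < 0.5

    def test_seed_determinism(self):
        a, _, _ = generate_planted(5, 50, 2, [(("S1", "S2"), "C1", 0.5)], seed=6)
        b, _, _ = generate_planted(5, 50, 2, [(("S1", "S2"), "C1", 0.5)], seed=6)
        assert np.array_equal(a.values, b.values)

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError, match="not a known block"):
            generate_planted(5, 50, 2, [(("S1", "S2"), "C9", 0.5)])

    def test_duplicate_copy_target_rejected(self):
        with pytest.raises(ValueError, match="copy target"):
            generate_planted(
                5, 50, 2,
                [(("S1", "S3"), "C1", 0.5), (("S2", "S3"), "C2", 0.5)],
            )
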
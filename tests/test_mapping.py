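from collections import Counter

import numpy as np
import pytest
from sklearn.base import clone

from doralisa import problems as pb
from doralisa.learning import best_target
from doralisa.mapping import (
    AnalogySolver,
    build_knowledge,
    encode_problem,
    infer_missing,
    map_analogs,
    solve_problem,
)
from doralisa.representations import DRIVER, Network, PO, RECIPIENT


def easy_problem(name="halving", seed=0):
    rng = np.random.default_rng(seed)
    feats = rng.choice(900, size=8, replace=False) + pb.FEATURE_OFFSET
    return pb.Problem(
        "easy",
        (pb.TransformationInstance(name, {name: 0}),),
        (frozenset(int(f) for f in feats[:4]),),
        (frozenset(int(f) for f in feats[4:]),),
    )


class TestMapAnalogs:
    def test_worked_containment_example(self, containment_pair, rng):
        net, driver, recipient, nm = containment_pair
        mapping = map_analogs(net, driver, recipient, 0.9, rng=rng)
        assert mapping.winner_of(nm["outside_d"]) == nm["outside_r"]
        assert mapping.winner_of(nm["inside_d"]) == nm["inside_r"]
        # featurally disjoint fillers map through shared role structure
        assert mapping.winner_of(nm["house"]) == nm["circle"]
        assert mapping.winner_of(nm["square"]) == nm["triangle"]
        assert mapping.winner_of(nm["p_d"]) == nm["p_r"]

    def test_self_mapping_is_identity_at_every_layer(self, rng):
        net = Network(pool_size=1000, inhibition=0.9)
        driver = net.new_analog(DRIVER)
        recipient = net.new_analog(RECIPIENT)
        pairs = {}
        for analog in (driver, recipient):
            out_p = net.add_po(
                analog.id, "predicate", dict.fromkeys(pb.ROLE_SEMANTICS["outside"], 1.0)
            )
            in_p = net.add_po(
                analog.id, "predicate", dict.fromkeys(pb.ROLE_SEMANTICS["inside"], 1.0)
            )
            a = net.create_object([300, 301, 302], analog.id)
            b = net.create_object([400, 401, 402], analog.id)
            top = net.make_proposition(
                [(out_p.id, a.id), (in_p.id, b.id)], analog.id
            )
            pairs[analog.id] = [out_p.id, in_p.id, a.id, b.id, top.id]
        mapping = map_analogs(net, driver.id, recipient.id, 0.9, rng=rng)
        for d, r in zip(pairs[driver.id], pairs[recipient.id]):
            assert mapping.winner_of(d) == r
        rb_d = sorted(net.tokens[pairs[driver.id][-1]].down)
        rb_r = sorted(net.tokens[pairs[recipient.id][-1]].down)
        for d, r in zip(rb_d, rb_r):
            assert mapping.winner_of(d) == r

    def test_winner_map_one_to_one_per_layer(self, clean_knowledge):
        rng = np.random.default_rng(4)
        for p in pb.generate_battery(15, rng):
            enc = encode_problem(p, clean_knowledge, 0.5)
            mapping = map_analogs(
                enc.net, enc.driver_id, enc.recipient_id, 0.5, rng=rng
            )
            for layer in ("PO", "RB", "P"):
                images = [
                    r for d, r in mapping.winners.items()
                    if enc.net.tokens[d].layer == layer
                ]
                assert len(images) == len(set(images))
                for d, r in mapping.winners.items():
                    assert enc.net.tokens[d].layer == enc.net.tokens[r].layer

    def test_empty_bank_rejected(self, rng):
        net = Network()
        d = net.new_analog(DRIVER)
        r = net.new_analog(RECIPIENT)
        net.create_object([50], d.id)
        with pytest.raises(ValueError):
            map_analogs(net, d.id, r.id, 0.8, rng=rng)


class TestInferMissing:
    def test_degenerate_analogy_reproduces_c_structure(self, clean_knowledge):
        # B identical to A: the generated D is structurally identical to C
        rng = np.random.default_rng(1)
        p = easy_problem()
        rec = solve_problem(p, clean_knowledge, 0.9, rng=rng)
        assert rec.outcome == "analogical"
        assert rec.n_inferred >= 1

    def test_no_mapping_refuses_inference(self, containment_pair, rng):
        net, driver, recipient, _ = containment_pair
        from doralisa.mapping import Mapping

        assert infer_missing(net, driver, recipient, Mapping(), 0.9, rng) == []

    def test_structure_preserved_when_mapping_complete(self, clean_knowledge):
        # with clean knowledge at strong inhibition, D mirrors B's role
        # skeleton: one inferred role-filler pair per encoded role
        rng = np.random.default_rng(2)
        p = easy_problem("doubling", seed=3)
        enc = encode_problem(p, clean_knowledge, 0.95)
        mapping = map_analogs(
            enc.net, enc.driver_id, enc.recipient_id, 0.95, rng=rng
        )
        inferred = infer_missing(
            enc.net, enc.driver_id, enc.recipient_id, mapping, 0.95, rng
        )
        assert len(inferred) == 1
        (rb,) = inferred
        assert best_target(rb.pred_weights)[0] == "doubling"
        assert rb.object_token == enc.c_object_tokens[0]
        enc.net.validate()


class TestSolveProblem:
    def test_easy_problem_solved_analogically_at_high_inhibition(
        self, clean_knowledge
    ):
        rng = np.random.default_rng(3)
        outcomes = [
            solve_problem(easy_problem(seed=s), clean_knowledge, 0.9, rng=rng).outcome
            for s in range(20)
        ]
        assert outcomes.count("analogical") >= 18

    def test_missing_predicate_blocks_that_transformation(self, clean_knowledge):
        knowledge = dict(clean_knowledge)
        knowledge["halving"] = None  # never learned
        rng = np.random.default_rng(4)
        rec = solve_problem(easy_problem("halving"), knowledge, 0.9, rng=rng)
        assert rec.outcome == "associative"
        two = pb.Problem(
            "medium",
            (
                pb.TransformationInstance("halving", {"halving": 0}),
                pb.TransformationInstance("doubling", {"doubling": 1}),
            ),
            (frozenset({500, 501, 502, 503}), frozenset({510, 511, 512, 513})),
            (frozenset({600, 601, 602, 603}), frozenset({610, 611, 612, 613})),
        )
        outcomes = Counter(
            solve_problem(two, knowledge, 0.9, rng=rng).outcome for _ in range(10)
        )
        assert outcomes["analogical"] == 0
        assert outcomes["incomplete"] >= 8  # doubling still inferred

    def test_accuracy_increases_with_inhibition_on_fixed_problems(
        self, clean_knowledge
    ):
        problems = pb.generate_battery(25, np.random.default_rng(8))
        correct = {}
        for lam in (0.2, 0.5, 0.8):
            rng = np.random.default_rng(99)
            n_ok = sum(
                solve_problem(p, clean_knowledge, lam, rng=rng).outcome
                == "analogical"
                for p in problems
                for _ in range(4)
            )
            correct[lam] = n_ok
        assert correct[0.2] <= correct[0.5] <= correct[0.8]

    def test_weak_inhibition_fails_hard_problems_more(self, clean_knowledge):
        problems = pb.generate_battery(40, np.random.default_rng(12))
        rng = np.random.default_rng(13)
        rate = {}
        for cls in ("easy", "hard"):
            subset = [p for p in problems if p.difficulty_class == cls]
            ok = [
                solve_problem(p, clean_knowledge, 0.4, rng=rng).outcome
                == "analogical"
                for p in subset
                for _ in range(5)
            ]
            rate[cls] = np.mean(ok)
        assert rate["hard"] < rate["easy"]


class TestBuildKnowledge:
    def test_selects_highest_quality_predicate(self):
        halving = sorted(pb.ROLE_SEMANTICS["halving"])
        ck_predicates = {
            1: {halving[0]: 1.0, halving[1]: 1.0, 40: 0.5, 41: 0.5},
            2: {halving[0]: 1.0, halving[1]: 1.0},
        }
        from doralisa.learning import Checkpoint

        ck = Checkpoint(100, ck_predicates, {1: 0.5, 2: 1.0})
        knowledge = build_knowledge(ck, retrieval_threshold=1.0)
        assert knowledge["halving"] == ck_predicates[2]
        assert knowledge["doubling"] is None

    def test_below_threshold_not_retrievable(self):
        halving = sorted(pb.ROLE_SEMANTICS["halving"])
        from doralisa.learning import Checkpoint

        ck = Checkpoint(100, {1: {halving[0]: 0.4}}, {1: 0.1})
        assert build_knowledge(ck, 1.0)["halving"] is None


class TestAnalogySolverEstimator:
    def test_fit_predict_interface(self, clean_knowledge):
        solver = AnalogySolver(inhibition=0.9, random_state=0).fit(clean_knowledge)
        problems = [easy_problem(seed=s) for s in range(5)]
        out = solver.predict(problems)
        assert out.shape == (5,)
        assert set(out) <= {"analogical", "incomplete", "associative"}

    def test_sklearn_param_interface(self):
        solver = AnalogySolver(inhibition=0.4, n_passes=5)
        params = solver.get_params()
        assert params["n_passes"] == 5
        assert clone(solver).get_params() == params

    def test_unfitted_predict_rejected(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            AnalogySolver().predict([easy_problem()])
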
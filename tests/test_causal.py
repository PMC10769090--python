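import numpy as np
import pandas as pd
import pytest

from reefscale import (
    CausalGraph,
    ace,
    apply_meek_r1,
    d_separated,
    discover,
    do_rule2_check,
    g2_test,
    genuine_cause_test,
    ic_skeleton,
    orient_v_structures,
    true_graph,
)
from dsep_oracle import d_separated_bruteforce, random_dag


def bernoulli_frame(rng, n, **probs):
    return pd.DataFrame(
        {k: (rng.uniform(size=n) < p).astype(int) for k, p in probs.items()}
    )


class TestG2:
    def test_exact_independence_gives_zero(self):
        # counts ((25,25),(25,25)): observed equals expected everywhere
        df = pd.DataFrame(
            {"x": [0] * 50 + [1] * 50, "y": ([0] * 25 + [1] * 25) * 2}
        )
        res = g2_test(df, "x", "y")
        assert res.g2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.independent

    def test_hand_computed_2x2(self):
        # counts ((30,10),(10,30)), expected 20 in every cell
        df = pd.DataFrame(
            {
                "x": [0] * 40 + [1] * 40,
                "y": [0] * 30 + [1] * 10 + [0] * 10 + [1] * 30,
            }
        )
        res = g2_test(df, "x", "y")
        assert res.g2 == pytest.approx(20.93, abs=0.01)
        assert res.df == 1
        assert res.dependent

    def test_equals_twice_n_mutual_information(self):
        rng = np.random.default_rng(2)
        df = bernoulli_frame(rng, 500, x=0.4, y=0.6)
        df["y"] = (df["y"] | df["x"]).astype(int)
        res = g2_test(df, "x", "y")
        joint = pd.crosstab(df["x"], df["y"]).to_numpy() / len(df)
        px, py = joint.sum(1), joint.sum(0)
        mi = sum(
            joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
            for i in range(2) for j in range(2) if joint[i, j] > 0
        )
        assert res.g2 == pytest.approx(2 * len(df) * mi)

    def test_conditional_df_counts_nonempty_strata(self):
        rng = np.random.default_rng(3)
        df = bernoulli_frame(rng, 400, x=0.5, y=0.5, a=0.5, b=0.5)
        res = g2_test(df, "x", "y", ("a", "b"))
        assert res.df == 4
        assert res.g2 >= 0

    def test_rough_type_i_calibration(self):
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(200):
            df = bernoulli_frame(rng, 500, x=0.5, y=0.5, s=0.5)
            rejections += g2_test(df, "x", "y", ("s",)).dependent
        assert 0.01 <= rejections / 200 <= 0.12

    def test_input_validation(self):
        df = pd.DataFrame({"x": [0, 1], "y": [1, 0]})
        with pytest.raises(ValueError):
            g2_test(df, "x", "x")
        with pytest.raises(ValueError):
            g2_test(df, "x", "y", ("x",))


class TestSkeleton:
    def test_chain_yields_two_edges_and_middle_separator(self):
        rng = np.random.default_rng(5)
        n = 8000
        x = (rng.uniform(size=n) < 0.5).astype(int)
        z = np.where(rng.uniform(size=n) < 0.8, x, 1 - x)
        y = np.where(rng.uniform(size=n) < 0.8, z, 1 - z)
        df = pd.DataFrame({"X": x, "Z": z, "Y": y})
        g = ic_skeleton(df)
        assert g.undirected == {frozenset("XZ"), frozenset("ZY")}
        assert g.sepsets[frozenset("XY")] == ("Z",)

    def test_independent_variables_give_empty_skeleton(self):
        rng = np.random.default_rng(6)
        df = bernoulli_frame(rng, 3000, a=0.5, b=0.4, c=0.6)
        g = ic_skeleton(df)
        assert not g.undirected

    def test_protection_scm_recovers_the_four_edges(self, scm_sample):
        _, data, _ = scm_sample
        g = ic_skeleton(data)
        assert g.undirected == {
            frozenset(("Human", "MPA")),
            frozenset(("TSA", "MPA")),
            frozenset(("Coral", "MPA")),
            frozenset(("MPA", "Structure")),
        }


class TestOrientation:
    def test_collider_recovered(self):
        # faithful collider: Z's probability rises additively with X and Y
        rng = np.random.default_rng(7)
        n = 8000
        x = (rng.uniform(size=n) < 0.5).astype(int)
        y = (rng.uniform(size=n) < 0.5).astype(int)
        z = (rng.uniform(size=n) < 0.1 + 0.4 * x + 0.4 * y).astype(int)
        g = orient_v_structures(ic_skeleton(pd.DataFrame({"X": x, "Y": y, "Z": z})))
        assert ("X", "Z") in g.directed and ("Y", "Z") in g.directed

    def test_chain_leaves_no_collider(self):
        rng = np.random.default_rng(8)
        n = 8000
        x = (rng.uniform(size=n) < 0.5).astype(int)
        z = np.where(rng.uniform(size=n) < 0.8, x, 1 - x)
        y = np.where(rng.uniform(size=n) < 0.8, z, 1 - z)
        g = orient_v_structures(ic_skeleton(pd.DataFrame({"X": x, "Z": z, "Y": y})))
        assert not g.directed

    def test_protection_scm_three_colliders_then_r1(self, scm_sample):
        _, data, _ = scm_sample
        g = orient_v_structures(ic_skeleton(data))
        for parent in ("Human", "TSA", "Coral"):
            assert (parent, "MPA") in g.directed
        g2 = apply_meek_r1(g)
        assert ("MPA", "Structure") in g2.directed
        assert not g2.undirected

    def test_r1_on_explicit_graph(self):
        g = CausalGraph(
            nodes=("a", "b", "c"),
            directed={("a", "b")},
            undirected={frozenset(("b", "c"))},
        )
        out = apply_meek_r1(g)
        assert ("b", "c") in out.directed and not out.undirected

    def test_r1_fixpoint_on_fully_directed_graph(self):
        g = CausalGraph(nodes=("a", "b"), directed={("a", "b")})
        assert apply_meek_r1(g).directed == {("a", "b")}


class TestDSeparation:
    def test_chain_and_collider_base_cases(self):
        chain = CausalGraph(nodes=("X", "Z", "Y"), directed={("X", "Z"), ("Z", "Y")})
        assert d_separated(chain, "X", "Y", {"Z"})
        assert not d_separated(chain, "X", "Y")
        collider = CausalGraph(nodes=("X", "Z", "Y"), directed={("X", "Z"), ("Y", "Z")})
        assert d_separated(collider, "X", "Y")
        assert not d_separated(collider, "X", "Y", {"Z"})

    def test_collider_opened_by_descendant(self):
        g = CausalGraph(
            nodes=("X", "Z", "Y", "D"),
            directed={("X", "Z"), ("Y", "Z"), ("Z", "D")},
        )
        assert not d_separated(g, "X", "Y", {"D"})

    def test_agrees_with_path_oracle_on_random_dags(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 1000:
            g = random_dag(6, 0.4, rng)
            nodes = list(g.nodes)
            x, y = rng.choice(6, size=2, replace=False)
            x, y = nodes[x], nodes[y]
            rest = [n for n in nodes if n not in (x, y)]
            z = {n for n in rest if rng.uniform() < 0.4}
            assert d_separated(g, x, y, z) == d_separated_bruteforce(g, x, y, z)
            checked += 1


class TestRule2:
    def test_protection_graph_licenses_observational_ace(self):
        g = true_graph()
        assert do_rule2_check(g, "Structure", "MPA")
        assert do_rule2_check(g, "Structure", "MPA", x={"Coral"}, w={"TSA"})

    def test_open_backdoor_blocks_exchange(self):
        g = CausalGraph(
            nodes=("U", "Z", "Y"), directed={("U", "Z"), ("U", "Y"), ("Z", "Y")}
        )
        assert not do_rule2_check(g, "Y", "Z")

    def test_disconnected_cause_is_vacuously_exchangeable(self):
        g = CausalGraph(nodes=("Z", "Y"), directed=set())
        assert do_rule2_check(g, "Y", "Z")


class TestGenuineCause:
    def test_faithful_scm_supports_genuine_cause(self, scm_sample):
        _, data, _ = scm_sample
        report = genuine_cause_test(data, "MPA", "Structure", ("Human", "TSA", "Coral"))
        assert report.step_i.dependent
        assert len(report.routes) == 6
        assert report.genuine
        assert report.n_routes_passed >= 4

    def test_independent_outcome_fails_step_one(self, scm_sample):
        _, data, _ = scm_sample
        rng = np.random.default_rng(10)
        shuffled = data.copy()
        shuffled["Structure"] = rng.permutation(shuffled["Structure"].to_numpy())
        report = genuine_cause_test(
            shuffled, "MPA", "Structure", ("Human", "TSA", "Coral")
        )
        assert not report.step_i.dependent
        assert not report.genuine

    def test_disconnected_candidate_breaks_its_routes(self, scm_sample):
        # replace Human by pure noise: routes with Z=Human lose the
        # Z-dependent-on-X requirement
        _, data, _ = scm_sample
        rng = np.random.default_rng(11)
        broken = data.copy()
        broken["Human"] = (rng.uniform(size=len(broken)) < 0.5).astype(int)
        report = genuine_cause_test(broken, "MPA", "Structure", ("Human", "TSA", "Coral"))
        for route in report.routes:
            if route.z == "Human":
                assert not route.passed

    def test_report_serializes(self, scm_sample):
        import json

        _, data, _ = scm_sample
        report = genuine_cause_test(data, "MPA", "Structure", ("Human", "TSA", "Coral"))
        payload = json.loads(json.dumps(report.to_dict()))
        assert payload["x"] == "MPA" and len(payload["routes"]) == 6


class TestACE:
    def test_arithmetic(self):
        df = pd.DataFrame(
            {"M": [1] * 50 + [0] * 100, "Y": [1] * 40 + [0] * 10 + [1] * 30 + [0] * 70}
        )
        assert ace(df, "M", "Y") == pytest.approx(0.5)

    def test_null_effect_vanishes(self):
        rng = np.random.default_rng(12)
        df = bernoulli_frame(rng, 20_000, M=0.5, Y=0.5)
        assert abs(ace(df, "M", "Y")) < 0.02

    def test_empty_arm_is_named(self):
        df = pd.DataFrame({"M": [1, 1], "Y": [0, 1]})
        with pytest.raises(ValueError, match="M=0"):
            ace(df, "M", "Y")


class TestDiscoverPipeline:
    def test_full_protection_graph_from_data(self, scm_sample):
        _, data, truth = scm_sample
        g = discover(data)
        assert g.directed == truth.graph.directed
        assert not g.undirected
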
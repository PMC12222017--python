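import itertools

import numpy as np
import pandas as pd
import pytest

from neckconn.connectivity import (
    average_by_type,
    build_partner_graph,
    class_composition,
    effective_connectivity,
    stereotypy_stats,
    synapse_density,
)


def edges_df(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "weight"])


@pytest.fixture()
def toy_graph():
    """5 neurons: focal f sends to in1 (strong), in2 (weak), mn (medium)."""
    edges = edges_df(
        [
            ("f", "in1", 20),
            ("f", "in2", 9),
            ("f", "mn", 6),
            ("in1", "f", 15),
            ("x", "in1", 80),
        ]
    )
    classes = {"f": "DN", "in1": "IN", "in2": "IN", "mn": "MN", "x": "IN"}
    return edges, classes


class TestPartnerGraph:
    def test_weight_below_threshold_excluded(self, toy_graph):
        edges, classes = toy_graph
        g = build_partner_graph({"f"}, edges, classes)
        assert "in2" not in set(g.nodes["node_id"])  # weight 9 < 10

    def test_motor_addback_at_lower_threshold(self, toy_graph):
        edges, classes = toy_graph
        g = build_partner_graph({"f"}, edges, classes)
        assert "mn" in set(g.nodes["node_id"])  # weight 6 >= 5 and MN

    def test_input_percent_matches_hand_computation(self, toy_graph):
        edges, classes = toy_graph
        g = build_partner_graph({"f"}, edges, classes)
        mat = g.input_pct_matrix()
        # in1 receives 20 of (20 + 80) = 20% from f
        assert mat.at["f", "in1"] == pytest.approx(20.0)
        # column sums never exceed 100
        assert (mat.sum(axis=0) <= 100 + 1e-6).all()

    def test_raising_any_threshold_never_adds_edges(self, toy_graph):
        edges, classes = toy_graph
        base = build_partner_graph({"f"}, edges, classes, theta_w=10, theta_pct=0.5, theta_sens=5)
        for kwargs in (
            dict(theta_w=21),
            dict(theta_pct=60.0),
            dict(theta_sens=7),
        ):
            stricter = build_partner_graph({"f"}, edges, classes, **kwargs)
            assert len(stricter.edges) <= len(base.edges)
            assert set(stricter.nodes["node_id"]) <= set(base.nodes["node_id"])

    def test_empty_focal_rejected(self, toy_graph):
        edges, classes = toy_graph
        with pytest.raises(ValueError, match="empty"):
            build_partner_graph(set(), edges, classes)

    def test_output_percent_measured_dataset_wide(self):
        # f's total output is 1000, so a weight-10 edge is 1% > 0.5% -> kept;
        # g's total output is 10000, so weight 10 is 0.1% -> dropped
        rows = [("f", "a", 10), ("f", "sink", 990), ("g", "b", 10), ("g", "sink", 9990)]
        classes = {k: "IN" for k in ("f", "g", "a", "b", "sink")}
        graph = build_partner_graph({"f", "g"}, edges_df(rows), classes, theta_w=10)
        assert "a" in set(graph.nodes["node_id"])
        assert "b" not in set(graph.nodes["node_id"])


class TestTypeAveraging:
    def test_mean_of_member_percents(self):
        edges = edges_df([("a1", "b1", 4), ("a2", "b1", 4), ("x", "b1", 192)])
        classes = {"a1": "DN", "a2": "DN", "b1": "IN", "x": "IN"}
        g = build_partner_graph({"a1", "a2"}, edges, classes, theta_w=4, theta_pct=0.1)
        tg = average_by_type(g, {"a1": "A", "a2": "A", "b1": "B", "x": "X"})
        # each member edge is 2% of b1's input; mean over the 2 member pairs
        row = tg.edges[(tg.edges["pre_id"] == "A") & (tg.edges["post_id"] == "B")]
        assert row["input_pct"].iloc[0] == pytest.approx(2.0)

    def test_member_order_invariant(self, toy_graph):
        edges, classes = toy_graph
        g = build_partner_graph({"f"}, edges, classes)
        tmap = {"f": "F", "in1": "I", "mn": "M", "x": "X"}
        t1 = average_by_type(g, tmap)
        g2 = build_partner_graph({"f"}, edges.iloc[::-1].reset_index(drop=True), classes)
        t2 = average_by_type(g2, tmap)
        e1 = t1.edges.sort_values(["pre_id", "post_id"]).reset_index(drop=True)
        e2 = t2.edges.sort_values(["pre_id", "post_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(e1, e2)


class TestClassComposition:
    def test_single_class_is_unity(self):
        edges = edges_df([("p1", "f", 5), ("p2", "f", 15)])
        comp = class_composition({"f"}, edges, {"p1": "SN", "p2": "SN", "f": "DN"}, "in")
        assert comp == {"SN": 1.0}

    def test_fractions_sum_to_one_and_match_hand_tally(self):
        edges = edges_df([("p1", "f", 30), ("p2", "f", 10), ("f", "q", 99)])
        comp = class_composition({"f"}, edges, {"p1": "SN", "p2": "IN", "f": "DN", "q": "MN"}, "in")
        assert sum(comp.values()) == pytest.approx(1.0)
        assert comp["SN"] == pytest.approx(0.75)
        assert comp["IN"] == pytest.approx(0.25)

    def test_no_partners_empty(self):
        assert class_composition({"f"}, edges_df([]), {}, "in") == {}


class TestStereotypy:
    def test_doubled_weights_slope_two(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = stereotypy_stats(a, 2 * a)
        assert out["slope_through_origin"] == pytest.approx(2.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_identical_vectors_slope_one(self):
        a = np.array([3.0, 1.0, 4.0])
        out = stereotypy_stats(a, a)
        assert out["slope_through_origin"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_matches_closed_form_on_four_point_toy(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 5.0, 9.0])
        out = stereotypy_stats(a, b)
        assert out["slope_through_origin"] == pytest.approx(np.sum(a * b) / np.sum(a * a))
        r = np.corrcoef(a, b)[0, 1]
        assert out["pearson_r"] == pytest.approx(r)

    def test_degenerate_input_reports_nan(self):
        out = stereotypy_stats([1.0], [2.0])
        assert np.isnan(out["pearson_r"])

    def test_lr_stereotypy_degrades_with_connection_noise(self):
        """Planted pair weights correlate strongly at low noise, less at high."""
        from neckconn.synthgen import SynthConfig, generate, tiny_config
        from neckconn.pipeline import _paired_output_weights
        from neckconn.matchpipe import pair_left_right

        rs = []
        for sigma_w in (0.0, 20.0):
            ds_f, _, truth, _ = generate(tiny_config(seed=5, sigma_w=sigma_w))
            focal = ds_f.neurons[ds_f.neurons["neuron_class"].isin(("DN", "AN"))]
            pairing = pair_left_right(ds_f, neuron_ids=focal["neuron_id"].tolist())
            a, b = _paired_output_weights(ds_f, pairing)
            rs.append(stereotypy_stats(a, b)["pearson_r"])
        assert rs[0] > 0.9
        assert rs[0] >= rs[1]


class TestEffectiveConnectivity:
    def test_direct_only_equals_input_fraction(self):
        edges = edges_df([("s", "t", 30), ("x", "t", 70)])
        eff = effective_connectivity({"s"}, {"t"}, edges, max_hops=1)
        assert eff["t"] == pytest.approx(0.3)

    def test_two_hop_product_rule(self):
        edges = edges_df([("s", "m", 1), ("y", "m", 1), ("m", "t", 1), ("z", "t", 1)])
        eff = effective_connectivity({"s"}, {"t"}, edges, max_hops=2)
        assert eff["t"] == pytest.approx(0.25)

    def test_matches_brute_force_path_enumeration(self, rng):
        """Exhaustive path-product enumeration on graphs of <= 8 nodes."""
        for trial in range(10):
            n = int(rng.integers(4, 9))
            ids = [f"n{i}" for i in range(n)]
            rows = [
                (ids[i], ids[j], int(rng.integers(1, 10)))
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < 0.4
            ]
            if not rows:
                continue
            edges = edges_df(rows)
            total_in = edges.groupby("post_id")["weight"].sum()
            frac = {
                (r.pre_id, r.post_id): r.weight / total_in[r.post_id]
                for r in edges.itertuples(index=False)
            }
            max_hops = 3
            source, target = ids[0], ids[-1]

            def paths_sum(cur, hops, product):
                total = 0.0
                if hops >= max_hops:
                    return 0.0
                for (pre, post), f in frac.items():
                    if pre == cur:
                        contrib = product * f
                        total += (contrib if post == target else 0.0) + paths_sum(
                            post, hops + 1, contrib
                        )
                return total

            want = paths_sum(source, 0, 1.0)
            got = effective_connectivity({source}, {target}, edges, max_hops=max_hops)[target]
            assert got == pytest.approx(want, abs=1e-12), trial

    def test_invalid_hops_rejected(self):
        with pytest.raises(ValueError):
            effective_connectivity({"a"}, {"b"}, edges_df([("a", "b", 1)]), max_hops=0)


class TestDensity:
    def syn_df(self, xyz, cleft=100.0):
        xyz = np.asarray(xyz, float)
        return pd.DataFrame(
            {
                "synapse_id": [f"s{i}" for i in range(len(xyz))],
                "neuron_id": "n",
                "role": "pre",
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "cleft_score": cleft,
                "neuropil": "",
            }
        )

    def test_single_voxel_count(self):
        grid = synapse_density(self.syn_df(np.full((10, 3), 1000.0)))
        assert grid.counts.shape == (1, 1, 1)
        assert grid.total == 10

    def test_total_count_conserved(self, rng):
        xyz = rng.uniform(0, 50_000, size=(200, 3))
        grid = synapse_density(self.syn_df(xyz))
        assert grid.total == 200

    def test_translation_covariance(self, rng):
        xyz = rng.uniform(0, 50_000, size=(100, 3))
        g1 = synapse_density(self.syn_df(xyz))
        g2 = synapse_density(self.syn_df(xyz + 5000.0))
        assert np.array_equal(g1.counts, g2.counts)
        assert np.allclose(g2.origin - g1.origin, 5000.0)

    def test_cleft_filter_is_strictly_greater(self):
        df = self.syn_df(np.zeros((3, 3)))
        df["cleft_score"] = [49.0, 50.0, 51.0]
        grid = synapse_density(df, cleft_min=50.0)
        assert grid.total == 1
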
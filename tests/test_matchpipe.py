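import itertools

import numpy as np
import pandas as pd
import pytest

from neckconn.matchpipe import (
    DimorphismLabel,
    MatchRecord,
    classify_dimorphism,
    confidence_bin,
    connectivity_fingerprint,
    cosine,
    cross_dataset_match,
    new_type_namer,
    pair_left_right,
)
from neckconn.morpho import fit_tps
from neckconn.pipeline import RunConfig, run_pipeline


def edges_df(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "weight"])


class TestFingerprint:
    def test_single_partner_is_one_hot(self):
        edges = edges_df([("n", "p", 7)])
        fp = connectivity_fingerprint("n", edges, {"p": "T1", "n": "T0"}, direction="out")
        assert fp.to_dict() == {"T1": 1.0}

    def test_scale_invariant_under_weight_doubling(self):
        edges = edges_df([("n", "p", 4), ("n", "q", 6), ("r", "n", 5)])
        tmap = {"p": "A", "q": "B", "r": "C", "n": "N"}
        doubled = edges.assign(weight=edges["weight"] * 2)
        pd.testing.assert_series_equal(
            connectivity_fingerprint("n", edges, tmap),
            connectivity_fingerprint("n", doubled, tmap),
        )

    def test_three_edge_toy_matches_hand_computation(self):
        edges = edges_df([("n", "p", 3), ("n", "q", 1), ("u", "n", 5)])
        tmap = {"p": "A", "q": "B", "u": "C", "n": "N"}
        fp = connectivity_fingerprint("n", edges, tmap, direction="both")
        assert fp["out:A"] == pytest.approx(0.75)
        assert fp["out:B"] == pytest.approx(0.25)
        assert fp["in:C"] == pytest.approx(1.0)

    def test_isolated_neuron_gives_zero_vector(self):
        fp = connectivity_fingerprint("lonely", edges_df([("a", "b", 1)]), {"a": "A", "b": "B"})
        assert len(fp) == 0


class TestCosine:
    def test_identical_orthogonal_and_zero(self):
        a = pd.Series({"x": 1.0, "y": 2.0})
        assert cosine(a, a) == pytest.approx(1.0)
        assert cosine(pd.Series({"x": 1.0}), pd.Series({"y": 1.0})) == 0.0
        assert cosine(pd.Series(dtype=float), a) == 0.0

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 1, size=6)
            b = rng.uniform(0, 1, size=6)
            want = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
            assert cosine(a, b) == pytest.approx(want)


class TestConfidence:
    def test_bins_and_high_is_above_three(self):
        assert confidence_bin(0.1) == 1
        assert confidence_bin(0.5) == 3
        assert confidence_bin(0.95) == 5
        # a confident match (combined > 0.6) maps to > 3
        assert confidence_bin(0.7) > 3


class TestPairing:
    def test_planted_pairs_recovered_without_false_pairs(self, tiny_bundle):
        ds_f, _, truth, _ = tiny_bundle
        focal = ds_f.neurons[ds_f.neurons["neuron_class"].isin(("DN", "AN"))]
        res = pair_left_right(ds_f, neuron_ids=focal["neuron_id"].tolist())
        got = {(l, r) for l, r, _ in res.pairs}
        want = {
            (r.left_id, r.right_id)
            for r in truth.pairs[truth.pairs["dataset_id"] == "F"].itertuples(index=False)
        }
        assert want <= got | {(l, r) for l, r, _ in res.pairs}
        # no pair joins different planted types
        ttype = dict(zip(truth.neurons["neuron_id"], truth.neurons["type"]))
        for l, r, _ in res.pairs:
            assert ttype[l] == ttype[r]

    def test_identical_twins_grouped_not_paired(self, tiny_bundle):
        """Population-type members are ambiguous and must form a group."""
        ds_f, _, truth, _ = tiny_bundle
        focal = ds_f.neurons[ds_f.neurons["neuron_class"].isin(("DN", "AN"))]
        res = pair_left_right(ds_f, neuron_ids=focal["neuron_id"].tolist())
        pop_types = truth.groups[truth.groups["dataset_id"] == "F"]["type"].tolist()
        assert pop_types
        paired_ids = {n for p in res.pairs for n in p[:2]}
        for t in pop_types:
            members = set(truth.groups.set_index(["dataset_id", "type"]).at[("F", t), "members"].split(";"))
            assert members & {m for g in res.groups for m in g}, "expected an ambiguity group"
            assert not members & paired_ids

    def test_empty_side_rejected(self, tiny_bundle):
        ds_f, _, _, _ = tiny_bundle
        only_right = ds_f.neurons[ds_f.neurons["side"] == "right"]["neuron_id"].tolist()
        with pytest.raises(ValueError):
            pair_left_right(ds_f, neuron_ids=only_right)


class TestCrossDatasetMatch:
    def test_identity_datasets_match_with_top_confidence(self, tiny_bundle):
        ds_f, _, _, _ = tiny_bundle
        lattice = np.array(
            [[x, y, z] for x in (0, 3e5) for y in (0, 1.5e5) for z in (0, 4e5)]
        )
        tps = fit_tps(lattice, lattice)  # identity transform
        records = cross_dataset_match(ds_f, ds_f, tps, classes=("DN", "AN"))
        matched = [r for r in records if r.status == "matched"]
        assert matched
        for r in matched:
            assert r.id_a == r.id_b
            assert r.confidence == 5

    def test_greedy_equals_optimal_assignment_when_separated(self, rng):
        """With well-separated scores greedy mutual-best is the optimum."""
        from scipy.optimize import linear_sum_assignment

        for trial in range(10):
            n = rng.integers(3, 9)
            scores = rng.uniform(0.0, 0.4, size=(n, n))
            perm = rng.permutation(n)
            for i, j in enumerate(perm):
                scores[i, j] = rng.uniform(0.8, 1.0)  # gap > 0.4 to distractors
            order = sorted(
                ((scores[i, j], i, j) for i in range(n) for j in range(n)),
                key=lambda t: -t[0],
            )
            used_a, used_b, greedy = set(), set(), {}
            for s, i, j in order:
                if i not in used_a and j not in used_b and s >= 0.5:
                    greedy[i] = j
                    used_a.add(i)
                    used_b.add(j)
            ri, cj = linear_sum_assignment(-scores)
            optimal = dict(zip(ri, cj))
            assert greedy == optimal

    def test_raising_threshold_never_adds_matches(self, tiny_bundle):
        ds_f, ds_m, _, _ = tiny_bundle
        src = ds_f.landmarks[["x_src", "y_src", "z_src"]].to_numpy(float)
        dst = ds_f.landmarks[["x_dst", "y_dst", "z_dst"]].to_numpy(float)
        tps = fit_tps(src, dst)
        counts = []
        for theta in (0.2, 0.4, 0.6, 0.8):
            rec = cross_dataset_match(ds_f, ds_m, tps, theta_match=theta, classes=("DN", "AN"))
            counts.append(sum(1 for r in rec if r.status == "matched"))
        assert counts == sorted(counts, reverse=True)

    def test_match_set_symmetric_under_dataset_swap(self, tiny_bundle):
        ds_f, ds_m, _, _ = tiny_bundle
        src = ds_f.landmarks[["x_src", "y_src", "z_src"]].to_numpy(float)
        dst = ds_f.landmarks[["x_dst", "y_dst", "z_dst"]].to_numpy(float)
        fwd = cross_dataset_match(ds_f, ds_m, fit_tps(src, dst), classes=("DN", "AN"))
        rev = cross_dataset_match(ds_m, ds_f, fit_tps(dst, src), classes=("DN", "AN"))
        fwd_pairs = {(r.id_a, r.id_b) for r in fwd if r.status == "matched"}
        rev_pairs = {(r.id_b, r.id_a) for r in rev if r.status == "matched"}
        assert fwd_pairs == rev_pairs

    def test_bad_weights_rejected(self, tiny_bundle):
        ds_f, ds_m, _, _ = tiny_bundle
        with pytest.raises(ValueError, match="sum to 1"):
            cross_dataset_match(ds_f, ds_m, lambda p: p, weights=(0.7, 0.4))

    def test_missing_transform_rejected(self, tiny_bundle):
        ds_f, ds_m, _, _ = tiny_bundle
        with pytest.raises(ValueError, match="transform"):
            cross_dataset_match(ds_f, ds_m, None)


class TestClassification:
    def test_every_neuron_gets_exactly_one_label(self, tiny_bundle):
        ds_f, ds_m, _, _ = tiny_bundle
        result = run_pipeline(ds_f, ds_m, RunConfig(runs=5))
        labelled = result.dimorphism["neuron_id"]
        assert labelled.is_unique
        focal_f = ds_f.neurons[ds_f.neurons["neuron_class"].isin(("DN", "AN"))]["neuron_id"]
        focal_m = ds_m.neurons[ds_m.neurons["neuron_class"].isin(("DN", "AN"))]["neuron_id"]
        assert set(focal_f) | set(focal_m) <= set(labelled)

    def test_planted_categories_recovered(self, tiny_bundle):
        ds_f, ds_m, truth, _ = tiny_bundle
        result = run_pipeline(ds_f, ds_m, RunConfig(runs=5))
        ttype = dict(zip(truth.neurons["neuron_id"], truth.neurons["type"]))
        want = dict(zip(truth.type_labels["type"], truth.type_labels["dimorphism_label"]))
        got = dict(zip(result.dimorphism["neuron_id"], result.dimorphism["label"]))
        for nid, label in got.items():
            assert label == want[ttype[nid]], (nid, label, want[ttype[nid]])

    def test_neuropeptidergic_flag_forces_exclusion(self, tiny_bundle):
        """An excluded flag dominates the cascade whatever the scores."""
        ds_f, ds_m, truth, _ = tiny_bundle
        excl_types = truth.type_labels[truth.type_labels["dimorphism_label"] == "excluded"]
        assert len(excl_types)
        result = run_pipeline(ds_f, ds_m, RunConfig(runs=5))
        ttype = dict(zip(truth.neurons["neuron_id"], truth.neurons["type"]))
        for nid, label, why in result.dimorphism.itertuples(index=False):
            if ttype[nid] in set(excl_types["type"]):
                assert label == "excluded"
                assert "neuropeptidergic" in why


class TestNaming:
    def test_new_type_numbering_starts_at_999_and_goes_down(self):
        namer = new_type_namer(prefix="DNxn")
        assert next(namer) == "DNxn999"
        assert next(namer) == "DNxn998"
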
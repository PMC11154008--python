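"""Metapath enumeration, DWPC, classifier training and evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from repomatch import hetnet
from repomatch.hetnet import (
    DwpcParams,
    HetGraph,
    Metapath,
    build_features,
    dwpc,
    enumerate_metapaths,
    evaluate_holdout,
    predict_treatments,
    sample_negative_pairs,
    train_model,
)
from repomatch.synthetic import SimulationSpec, generate_hetnet


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_oracle(schema, max_length, source="DRUG", target="DISEASE"):
    triples = set()
    for a, r, b in schema:
        triples.add((a, r, b))
        triples.add((b, r, a))
    out = []

    def rec(path, at):
        if path and at == target:
            out.append(tuple(path))
        if len(path) == max_length:
            return
        for t0, r, t1 in triples:
            if t0 == at:
                rec(path + [(t0, r, t1)], t1)

    rec([], source)
    return {tuple(p) for p in out}


def dwpc_oracle(graph: HetGraph, metapath: Metapath, source, target, w):
    """Enumerate all conforming simple paths; multiply explicit degree terms."""

    def degree(node, rel, ntype):
        return sum(
            1
            for s, r, t in graph.edges
            if r == rel
            and (
                (s == node and graph.nodes[t] == ntype)
                or (t == node and graph.nodes[s] == ntype)
            )
        )

    total = 0.0

    def rec(node, depth, visited, weight):
        nonlocal total
        if depth == len(metapath.steps):
            if node == target:
                total += weight
            return
        t0, rel, t1 = metapath.steps[depth]
        for s, r, t in graph.edges:
            if r != rel:
                continue
            nxt = None
            if s == node and graph.nodes[t] == t1:
                nxt = t
            elif t == node and graph.nodes[s] == t1:
                nxt = s
            if nxt is None or nxt in visited:
                continue
            if depth == len(metapath.steps) - 1 and nxt != target:
                continue
            term = (degree(node, rel, t1) * degree(nxt, rel, t0)) ** (-w)
            rec(nxt, depth + 1, visited | {nxt}, weight * term)

    rec(source, 0, {source}, 1.0)
    return total


def random_hetgraph(rng: np.random.Generator) -> HetGraph:
    """Random typed graph on <= 8 nodes over a tiny 4-type schema."""
    counts = {
        "DRUG": int(rng.integers(1, 3)),
        "GENE": int(rng.integers(1, 3)),
        "ANAT": int(rng.integers(1, 3)),
        "DISEASE": int(rng.integers(1, 3)),
    }
    nodes = {}
    for t, c in counts.items():
        for i in range(c):
            nodes[f"{t.lower()}{i}"] = t
    allowed = [
        ("DRUG", "targets", "GENE"),
        ("GENE", "assoc", "DISEASE"),
        ("GENE", "expressed", "ANAT"),
        ("ANAT", "site_of", "DISEASE"),
        ("DRUG", "treats", "DISEASE"),
        ("GENE", "interacts", "GENE"),
    ]
    edges = []
    names = sorted(nodes)
    for a, rel, b in allowed:
        pool = [
            (x, y)
            for x in names
            for y in names
            if x != y and nodes[x] == a and nodes[y] == b
        ]
        for x, y in pool:
            if rng.random() < 0.6:
                edges.append((x, rel, y))
    return HetGraph(nodes, edges, node_types=set(counts))


# ---------------------------------------------------------------------------


class TestEnumerateMetapaths:
    def test_forced_single_metapath(self):
        schema = {("DRUG", "targets", "GENE"), ("GENE", "assoc", "DISEASE")}
        mps = enumerate_metapaths(schema, 2)
        assert len(mps) == 1
        assert str(mps[0]) == "DRUG-targets-GENE-assoc-DISEASE"

    def test_no_direct_relation_at_length_one(self):
        schema = {("DRUG", "targets", "GENE"), ("GENE", "assoc", "DISEASE")}
        assert enumerate_metapaths(schema, 1) == []

    def test_invalid_max_length(self):
        with pytest.raises(ValueError):
            enumerate_metapaths({("DRUG", "treats", "DISEASE")}, 0)

    def test_matches_brute_force_on_toy_schema(self):
        schema = {
            ("DRUG", "targets", "GENE"),
            ("GENE", "assoc", "DISEASE"),
            ("GENE", "expressed", "ANAT"),
            ("ANAT", "site_of", "DISEASE"),
            ("DRUG", "treats", "DISEASE"),
        }
        got = {m.steps for m in enumerate_metapaths(schema, 3)}
        assert got == enumerate_oracle(schema, 3)

    def test_deterministic_order(self):
        schema = {("DRUG", "treats", "DISEASE"), ("DISEASE", "assoc", "GENE"),
                  ("DRUG", "targets", "GENE")}
        a = [str(m) for m in enumerate_metapaths(schema, 3)]
        b = [str(m) for m in enumerate_metapaths(set(reversed(list(schema))), 3)]
        assert a == b


MP_DGD = Metapath((("DRUG", "targets", "GENE"), ("GENE", "assoc", "DISEASE")))


class TestDwpc:
    def test_unique_path_with_unit_degrees_is_one_for_any_w(self):
        g = HetGraph(
            {"d": "DRUG", "g": "GENE", "z": "DISEASE"},
            [("d", "targets", "g"), ("g", "assoc", "z")],
        )
        for w in (0.0, 0.4, 1.0, 3.0):
            assert dwpc(g, MP_DGD, "d", "z", DwpcParams(w)) == pytest.approx(1.0)

    def test_no_conforming_path_is_zero(self):
        g = HetGraph(
            {"d": "DRUG", "g": "GENE", "z": "DISEASE"}, [("d", "targets", "g")]
        )
        assert dwpc(g, MP_DGD, "d", "z") == 0.0

    def test_seven_node_toy_with_degree_two_intermediate(self):
        # two genes bridge d->z; g1 also targets a second drug (degree 2)
        g = HetGraph(
            {
                "d": "DRUG", "d2": "DRUG", "g1": "GENE", "g2": "GENE",
                "z": "DISEASE", "z2": "DISEASE", "g3": "GENE",
            },
            [
                ("d", "targets", "g1"),
                ("d", "targets", "g2"),
                ("d2", "targets", "g1"),
                ("g1", "assoc", "z"),
                ("g2", "assoc", "z"),
                ("g2", "assoc", "z2"),
                ("d2", "targets", "g3"),
            ],
        )
        w = 0.4
        # path d-g1-z: d targets-degree 2, g1 targets-degree 2; g1 assoc 1, z assoc 2
        p1 = (2 * 2) ** -w * (1 * 2) ** -w
        # path d-g2-z: g2 targets-degree 1; g2 assoc 2, z assoc 2
        p2 = (2 * 1) ** -w * (2 * 2) ** -w
        got = dwpc(g, MP_DGD, "d", "z", DwpcParams(w))
        assert got == pytest.approx(p1 + p2, abs=1e-12)
        assert got == pytest.approx(dwpc_oracle(g, MP_DGD, "d", "z", w), abs=1e-12)

    def test_type_mismatch_raises(self):
        g = HetGraph({"d": "DRUG", "z": "DISEASE"}, [("d", "treats", "z")])
        with pytest.raises(ValueError):
            dwpc(g, MP_DGD, "z", "d")

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(8)
        schema = {
            ("DRUG", "targets", "GENE"),
            ("GENE", "assoc", "DISEASE"),
            ("GENE", "expressed", "ANAT"),
            ("ANAT", "site_of", "DISEASE"),
            ("DRUG", "treats", "DISEASE"),
            ("GENE", "interacts", "GENE"),
        }
        metapaths = enumerate_metapaths(schema, 3)
        checked = 0
        for _ in range(40):
            g = random_hetgraph(rng)
            drugs = g.nodes_of_type("DRUG")
            diseases = g.nodes_of_type("DISEASE")
            mp = metapaths[int(rng.integers(0, len(metapaths)))]
            src = drugs[int(rng.integers(0, len(drugs)))]
            dst = diseases[int(rng.integers(0, len(diseases)))]
            w = float(rng.uniform(0, 1))
            got = dwpc(g, mp, src, dst, DwpcParams(w))
            assert got == pytest.approx(
                dwpc_oracle(g, mp, src, dst, w), abs=1e-12
            )
            checked += 1
        assert checked == 40

    def test_w_zero_is_integer_path_count(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = random_hetgraph(rng)
            for src in g.nodes_of_type("DRUG"):
                for dst in g.nodes_of_type("DISEASE"):
                    count = dwpc(g, MP_DGD, src, dst, DwpcParams(0.0))
                    assert count == int(round(count))

    def test_monotone_non_increasing_in_w(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            g = random_hetgraph(rng)
            src = g.nodes_of_type("DRUG")[0]
            dst = g.nodes_of_type("DISEASE")[0]
            values = [
                dwpc(g, MP_DGD, src, dst, DwpcParams(w))
                for w in (0.0, 0.2, 0.4, 0.8, 1.5)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestGraphStructure:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            HetGraph({"a": "DRUG"}, [("a", "treats", "a")])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            HetGraph({"a": "DRUG"}, [("a", "treats", "zz")])

    def test_tsv_roundtrip(self, tmp_path):
        g = HetGraph(
            {"d": "DRUG", "g": "GENE", "z": "DISEASE"},
            [("d", "targets", "g"), ("g", "assoc", "z")],
        )
        hetnet.write_hetgraph_tsv(g, tmp_path / "edges.tsv")
        back = hetnet.load_hetgraph_tsv(tmp_path / "edges.tsv")
        assert back.nodes == g.nodes
        assert sorted(back.edges) == sorted(g.edges)


class TestFeaturesAndMasking:
    def test_disconnected_pair_yields_zero_row(self):
        g = HetGraph(
            {"d": "DRUG", "g": "GENE", "z": "DISEASE", "z2": "DISEASE"},
            [("d", "targets", "g"), ("g", "assoc", "z")],
        )
        feats = build_features(g, [("d", "z2")], [MP_DGD])
        assert (feats[[str(MP_DGD)]].to_numpy() == 0).all()

    def test_own_treat_edge_masked_from_feature(self):
        mp = Metapath(
            (("DRUG", "treats", "DISEASE"), ("DISEASE", "assoc", "GENE"),
             ("GENE", "assoc", "DISEASE"))
        )
        g = HetGraph(
            {"d": "DRUG", "z1": "DISEASE", "z2": "DISEASE", "g": "GENE"},
            [
                ("d", "treats", "z1"),
                ("z1", "assoc", "g"),
                ("g", "assoc", "z2"),
            ],
        )
        masked = build_features(g, [("d", "z2")], [mp], mask_own_edge=True)
        open_ = build_features(g, [("d", "z2")], [mp], mask_own_edge=False)
        # the d-treats-z1 edge is not the pair's own edge: identical either way
        assert masked.iloc[0, 0] == open_.iloc[0, 0] > 0
        own = build_features(g, [("d", "z1")], [mp], mask_own_edge=True)
        assert own.iloc[0, 0] == 0.0  # its own treats edge is removed
        own_open = build_features(g, [("d", "z1")], [mp], mask_own_edge=False)
        assert own_open.iloc[0, 0] == 0.0  # z1 cannot be interior and target
        # masking restores the graph afterwards
        assert g.has_edge("d", "treats", "z1")


def _toy_features(n=60, separate=True, seed=0):
    rng = np.random.default_rng(seed)
    # uniform bands with a hard margin: feature 1 perfectly separates classes
    lo = 2.0 if separate else 0.0
    pos = np.column_stack([rng.uniform(lo, lo + 1, n // 2), rng.normal(size=n // 2)])
    neg = np.column_stack([rng.uniform(0.0, 1.0, n - n // 2), rng.normal(size=n - n // 2)])
    frame = pd.DataFrame(
        np.vstack([pos, neg]), columns=["m1", "m2"],
        index=pd.MultiIndex.from_tuples(
            [(f"d{i}", "z") for i in range(n)], names=["drug", "disease"]
        ),
    )
    frame["label"] = ["positive"] * (n // 2) + ["negative"] * (n - n // 2)
    return frame


class TestTrainAndEvaluate:
    def test_separating_feature_reaches_training_accuracy_one(self):
        feats = _toy_features(separate=True)
        model = train_model(feats, seed=0)
        scores = model.scores(feats)
        y = (feats["label"] == "positive").to_numpy()
        assert ((scores >= 0.5) == y).mean() == 1.0

    def test_single_class_raises(self):
        feats = _toy_features()
        feats["label"] = "positive"
        with pytest.raises(ValueError):
            train_model(feats, seed=0)

    def test_auc_pairwise_counting_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.random(50) < 0.4
        s = rng.normal(size=50)
        wins = ties = 0
        for i in np.flatnonzero(y):
            for j in np.flatnonzero(~y):
                wins += s[i] > s[j]
                ties += s[i] == s[j]
        expected = (wins + 0.5 * ties) / (y.sum() * (~y).sum())
        assert roc_auc_score(y, s) == pytest.approx(expected, abs=1e-12)

    def test_constant_scores_give_auc_half(self):
        y = np.array([1, 1, 0, 0, 0])
        assert roc_auc_score(y, np.ones(5)) == pytest.approx(0.5)

    def test_label_shuffle_destroys_holdout_signal(self):
        spec = SimulationSpec(seed=17)
        graph, labels = generate_hetnet(spec)
        mps = enumerate_metapaths(graph.metaedges(), 3)
        pos = [(r.drug, r.disease) for r in labels.itertuples() if r.split == "train"]
        neg = sample_negative_pairs(graph, pos, 4.0, np.random.default_rng(17))
        pairs = pos + neg
        aucs = []
        for shuffle in range(5):
            rng = np.random.default_rng(100 + shuffle)
            perm = rng.permutation(len(pairs))
            fake_pos = [pairs[i] for i in perm[: len(pos)]]
            fake_neg = [pairs[i] for i in perm[len(pos):]]
            metrics = evaluate_holdout(
                graph, fake_pos, fake_neg, mps, k_folds=5, seed=shuffle
            )
            aucs.append(metrics["auc"])
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_evaluation_reproducible_given_seed(self):
        spec = SimulationSpec(seed=17)
        graph, labels = generate_hetnet(spec)
        mps = enumerate_metapaths(graph.metaedges(), 3)
        pos = [(r.drug, r.disease) for r in labels.itertuples() if r.split == "train"]
        neg = sample_negative_pairs(graph, pos, 4.0, np.random.default_rng(17))
        a = evaluate_holdout(graph, pos, neg, mps, k_folds=3, seed=17)
        b = evaluate_holdout(graph, pos, neg, mps, k_folds=3, seed=17)
        assert a == b

    def test_empty_holdout_raises(self):
        spec = SimulationSpec(seed=17)
        graph, _ = generate_hetnet(spec)
        mps = enumerate_metapaths(graph.metaedges(), 3)
        with pytest.raises(ValueError):
            evaluate_holdout(graph, [], [], mps)


class TestPredictTreatments:
    def _fitted(self, graph, mps, labels, seed=17):
        pos = [(r.drug, r.disease) for r in labels.itertuples() if r.split == "train"]
        neg = sample_negative_pairs(graph, pos, 4.0, np.random.default_rng(seed))
        feats = build_features(
            graph, pos + neg, mps,
            labels=["positive"] * len(pos) + ["negative"] * len(neg),
        )
        return train_model(feats, seed=seed)

    def test_single_candidate_ranks_first(self):
        spec = SimulationSpec(seed=17)
        graph, labels = generate_hetnet(spec)
        mps = enumerate_metapaths(graph.metaedges(), 3)
        model = self._fitted(graph, mps, labels)
        disease = labels["disease"].iloc[0]
        pred = predict_treatments(
            model, graph, disease, candidate_drugs=["drug_000"], metapaths=mps
        )
        assert len(pred) == 1 and pred["drug_id"].iloc[0] == "drug_000"

    def test_zero_feature_candidate_is_flagged(self):
        g = HetGraph(
            {"d": "DRUG", "g": "GENE", "z": "DISEASE", "d2": "DRUG"},
            [("d", "targets", "g"), ("g", "assoc", "z"), ("d", "treats", "z")],
        )
        feats = build_features(
            g, [("d", "z"), ("d2", "z")], [MP_DGD],
            labels=["positive", "negative"], mask_own_edge=False,
        )
        model = train_model(
            pd.concat([feats] * 10), seed=0
        )
        pred = predict_treatments(model, g, "z", metapaths=[MP_DGD])
        flagged = dict(zip(pred["drug_id"], pred["flag"]))
        assert flagged["d2"] == "disconnected-features"
        assert flagged["d"] == ""

    def test_missing_disease_raises(self):
        g = HetGraph({"d": "DRUG"}, [])
        with pytest.raises(ValueError):
            predict_treatments(None, g, "nope", metapaths=[MP_DGD])
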
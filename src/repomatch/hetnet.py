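"""Treatment prediction on a typed heterogeneous graph (hetnet).

Drug–disease pairs are featurised by the degree-weighted path count (DWPC)
along each type-consistent metapath: the sum over metapath-conforming
simple paths (no repeated nodes) of the path-degree product
``prod (d_source * d_target) ** (-w)``, where for each traversed edge the
degrees are metaedge-specific — the number of same-relation edges the
source node has toward the target's type, and vice versa. The damping
exponent ``w`` (default 0.4) down-weights hub-mediated paths; ``w = 0``
recovers the raw path count.

A small neural classifier (one 16-unit rectifier hidden layer, logistic
output) is trained on DWPC features of known treatment edges versus sampled
negatives. Each positive pair's own treats edge is masked from the graph
while its features are computed, and held-out evaluation masks each test
fold's treat edges wholesale, so path counts never see the label being
predicted.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "HetGraph",
    "Metapath",
    "DwpcParams",
    "TreatmentModel",
    "enumerate_metapaths",
    "dwpc",
    "build_features",
    "sample_negative_pairs",
    "train_model",
    "evaluate_holdout",
    "predict_treatments",
    "load_hetgraph_tsv",
    "write_hetgraph_tsv",
]

TREATS = "treats"


@dataclass(frozen=True)
class Metapath:
    """Alternating type/relation sequence constraining paths, DRUG→DISEASE.

    Stored as a tuple of steps ``(source_type, relation, target_type)``.
    """

    steps: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("empty metapath")
        for (_, _, t1), (t2, _, _) in zip(self.steps, self.steps[1:]):
            if t1 != t2:
                raise ValueError("metapath steps are not chained")

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def source_type(self) -> str:
        return self.steps[0][0]

    @property
    def target_type(self) -> str:
        return self.steps[-1][2]

    def __str__(self) -> str:
        parts = [self.steps[0][0]]
        for _, rel, t in self.steps:
            parts += [rel, t]
        return "-".join(parts)


@dataclass
class DwpcParams:
    """DWPC hyper-parameters: damping exponent and metapath length cap."""

    damping_exponent: float = 0.4
    max_metapath_length: int = 3

    def __post_init__(self) -> None:
        if self.damping_exponent < 0:
            raise ValueError("damping exponent must be >= 0")


class HetGraph:
    """Typed undirected multigraph with relation-labelled edges.

    Adjacency is indexed by ``(node, relation, neighbour_type)`` so that
    metaedge-specific degrees — the quantities DWPC damps by — are O(1).
    """

    def __init__(
        self,
        nodes: dict[str, str],
        edges: Iterable[tuple[str, str, str]],
        node_types: set[str] | None = None,
    ):
        self.nodes: dict[str, str] = dict(nodes)
        self.node_types: set[str] = set(node_types or set(self.nodes.values()))
        unknown = set(self.nodes.values()) - self.node_types
        if unknown:
            raise ValueError(f"nodes with types outside the schema: {unknown}")
        self._adj: dict[tuple[str, str, str], set[str]] = {}
        self.edges: list[tuple[str, str, str]] = []
        for s, rel, t in edges:
            self.add_edge(s, rel, t)

    def add_edge(self, s: str, rel: str, t: str) -> None:
        if s == t:
            raise ValueError(f"self-loop on {s!r}")
        for u in (s, t):
            if u not in self.nodes:
                raise ValueError(f"edge endpoint {u!r} is not a declared node")
        key_st = (s, rel, self.nodes[t])
        if t in self._adj.get(key_st, ()):  # de-duplicate parallel edges
            return
        self._adj.setdefault(key_st, set()).add(t)
        self._adj.setdefault((t, rel, self.nodes[s]), set()).add(s)
        self.edges.append((s, rel, t))

    def has_edge(self, s: str, rel: str, t: str) -> bool:
        return t in self._adj.get((s, rel, self.nodes.get(t, "")), ())

    def neighbors(self, node: str, rel: str, neighbor_type: str) -> set[str]:
        return self._adj.get((node, rel, neighbor_type), set())

    def degree(self, node: str, rel: str, neighbor_type: str) -> int:
        """Metaedge-specific degree: #``rel`` edges from ``node`` to that type."""
        return len(self._adj.get((node, rel, neighbor_type), ()))

    def metaedges(self) -> set[tuple[str, str, str]]:
        """Schema triples (type_a, relation, type_b), canonically ordered."""
        out = set()
        for s, rel, t in self.edges:
            ta, tb = sorted((self.nodes[s], self.nodes[t]))
            out.add((ta, rel, tb))
        return out

    @contextmanager
    def masked(self, edges: Iterable[tuple[str, str, str]]) -> Iterator[None]:
        """Temporarily remove edges (either endpoint order) from adjacency."""
        removed: list[tuple[str, str, str]] = []
        for s, rel, t in edges:
            if t in self._adj.get((s, rel, self.nodes[t]), ()):
                self._adj[(s, rel, self.nodes[t])].discard(t)
                self._adj[(t, rel, self.nodes[s])].discard(s)
                removed.append((s, rel, t))
        try:
            yield
        finally:
            for s, rel, t in removed:
                self._adj[(s, rel, self.nodes[t])].add(t)
                self._adj[(t, rel, self.nodes[s])].add(s)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t == node_type)


def enumerate_metapaths(
    schema: Iterable[tuple[str, str, str]],
    max_length: int,
    source_type: str = "DRUG",
    target_type: str = "DISEASE",
) -> list[Metapath]:
    """All type-consistent source→target metapaths up to ``max_length`` edges.

    ``schema`` is a set of undirected metaedges (type_a, relation, type_b);
    each may be traversed in either orientation. Output order is
    deterministic: by length, then by string form.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    triples = set()
    for ta, rel, tb in schema:
        triples.add((ta, rel, tb))
        triples.add((tb, rel, ta))
    found: list[Metapath] = []

    def extend(current: tuple[tuple[str, str, str], ...], at: str) -> None:
        if current and at == target_type:
            found.append(Metapath(current))
        if len(current) == max_length:
            return
        for t0, rel, t1 in sorted(triples):
            if t0 == at:
                extend(current + ((t0, rel, t1),), t1)

    extend((), source_type)
    return sorted(found, key=lambda m: (m.length, str(m)))


def dwpc(
    graph: HetGraph,
    metapath: Metapath,
    source: str,
    target: str,
    params: DwpcParams | None = None,
) -> float:
    """Degree-weighted path count between two nodes along one metapath.

    Sums, over all node-disjoint paths conforming to the metapath, the
    product over traversed edges of ``(d_source * d_target) ** (-w)`` with
    metaedge-specific degrees. Returns 0 when no conforming path exists.
    """
    params = params or DwpcParams()
    w = params.damping_exponent
    for node, expected in ((source, metapath.source_type), (target, metapath.target_type)):
        actual = graph.nodes.get(node)
        if actual != expected:
            raise ValueError(
                f"node {node!r} has type {actual!r}, metapath expects {expected!r}"
            )
    steps = metapath.steps
    total = 0.0

    def walk(node: str, depth: int, visited: set[str], weight: float) -> None:
        nonlocal total
        if depth == len(steps):
            if node == target:
                total += weight
            return
        t0, rel, t1 = steps[depth]
        last = depth == len(steps) - 1
        # sorted iteration: float accumulation order must not depend on
        # set-internal state, or repeated runs drift at ULP level
        for nxt in sorted(graph.neighbors(node, rel, t1)):
            if nxt in visited:
                continue
            if last and nxt != target:
                continue
            d_src = graph.degree(node, rel, t1)
            d_tgt = graph.degree(nxt, rel, t0)
            step_w = weight * (d_src * d_tgt) ** (-w)
            visited.add(nxt)
            walk(nxt, depth + 1, visited, step_w)
            visited.discard(nxt)

    walk(source, 0, {source}, 1.0)
    return total


def build_features(
    graph: HetGraph,
    pairs: Sequence[tuple[str, str]],
    metapaths: Sequence[Metapath],
    params: DwpcParams | None = None,
    labels: Sequence[str] | None = None,
    treat_relation: str = TREATS,
    mask_own_edge: bool = True,
    extra_masked_edges: Iterable[tuple[str, str, str]] = (),
) -> pd.DataFrame:
    """DWPC feature matrix for drug–disease pairs.

    Rows are indexed by ``(drug, disease)``; columns are metapath strings
    plus a ``label`` column (``positive`` / ``negative`` / ``unlabeled``).
    With ``mask_own_edge`` each pair's own treats edge is removed from the
    graph while that row is computed, preventing the label edge from
    contributing to its own features; ``extra_masked_edges`` are removed
    for every row (used for held-out folds).
    """
    params = params or DwpcParams()
    if labels is not None and len(labels) != len(pairs):
        raise ValueError("labels and pairs length mismatch")
    extra = list(extra_masked_edges)
    rows = []
    with graph.masked(extra):
        for i, (drug, disease) in enumerate(pairs):
            own = [(drug, treat_relation, disease)] if mask_own_edge else []
            with graph.masked(own):
                values = [
                    dwpc(graph, mp, drug, disease, params) for mp in metapaths
                ]
            rows.append(values)
    index = pd.MultiIndex.from_tuples(pairs, names=["drug", "disease"])
    matrix = pd.DataFrame(rows, index=index, columns=[str(m) for m in metapaths])
    matrix["label"] = list(labels) if labels is not None else "unlabeled"
    return matrix


def sample_negative_pairs(
    graph: HetGraph,
    positives: Sequence[tuple[str, str]],
    ratio: float = 4.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Sample non-treat drug–disease pairs at ``ratio`` : 1.

    Drugs and diseases are drawn with probability proportional to their
    positive-pair frequency plus one, so negatives roughly match the degree
    profile of the positives.
    """
    rng = rng or np.random.default_rng()
    drugs = graph.nodes_of_type("DRUG")
    diseases = graph.nodes_of_type("DISEASE")
    pos_set = set(positives)
    drug_w = np.array([sum(d == p[0] for p in positives) + 1 for d in drugs], float)
    dis_w = np.array([sum(d == p[1] for p in positives) + 1 for d in diseases], float)
    drug_w /= drug_w.sum()
    dis_w /= dis_w.sum()
    wanted = int(round(ratio * len(positives)))
    chosen: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    attempts = 0
    while len(chosen) < wanted and attempts < 100 * wanted:
        attempts += 1
        pair = (
            drugs[rng.choice(len(drugs), p=drug_w)],
            diseases[rng.choice(len(diseases), p=dis_w)],
        )
        if pair in pos_set or pair in seen:
            continue
        seen.add(pair)
        chosen.append(pair)
    return chosen


@dataclass
class TreatmentModel:
    """Fitted treatment classifier plus the metadata to reproduce it."""

    pipeline: Pipeline
    feature_names: list[str]
    seed: int
    n_positive: int
    n_negative: int

    def scores(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy(dtype=float)
        return self.pipeline.predict_proba(x)[:, 1]

    def to_json(self, path: str | Path) -> None:
        mlp: MLPClassifier = self.pipeline.named_steps["mlp"]
        scaler: StandardScaler = self.pipeline.named_steps["scale"]
        payload = {
            "feature_names": self.feature_names,
            "seed": self.seed,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "scaler_mean": scaler.mean_.tolist(),
            "scaler_scale": scaler.scale_.tolist(),
            "coefs": [c.tolist() for c in mlp.coefs_],
            "intercepts": [b.tolist() for b in mlp.intercepts_],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


def _feature_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c != "label"]


def train_model(features: pd.DataFrame, seed: int = 0) -> TreatmentModel:
    """Fit the treatment classifier on a labelled DWPC feature matrix.

    Architecture: standardised inputs, one 16-unit ReLU hidden layer,
    logistic output, trained to loss convergence. At desk-scale sample
    sizes a held-back validation split is too small to steer early
    stopping reliably (the restored best-validation snapshot is an
    underfit lottery), so regularisation rests on the default L2 penalty.
    Training is deterministic given the seed.
    """
    labelled = features[features["label"].isin(["positive", "negative"])]
    y = (labelled["label"] == "positive").to_numpy()
    if y.all() or not y.any():
        raise ValueError("training requires both positive and negative labels")
    cols = _feature_columns(labelled)
    x = labelled[cols].to_numpy(dtype=float)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(16,),
                    activation="relu",
                    solver="adam",
                    learning_rate_init=0.01,
                    max_iter=2000,
                    tol=1e-5,
                    n_iter_no_change=50,
                    random_state=int(seed) % (2**31),
                ),
            ),
        ]
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # the iteration cap doubles as regularisation; hitting it is expected
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(x, y)
    return TreatmentModel(pipe, cols, int(seed), int(y.sum()), int((~y).sum()))


def evaluate_holdout(
    graph: HetGraph,
    positives: Sequence[tuple[str, str]],
    negatives: Sequence[tuple[str, str]],
    metapaths: Sequence[Metapath],
    params: DwpcParams | None = None,
    k_folds: int = 5,
    seed: int = 0,
    treat_relation: str = TREATS,
) -> dict:
    """Leak-free k-fold evaluation of the treatment classifier.

    Pairs are split into folds; for each fold, features of the held-out
    pairs are recomputed with *all* of that fold's treat edges removed from
    the graph, a fresh model is fit on the remaining folds, and AUC / F1
    (threshold 0.5) are measured on the held-out pairs. Returns the means
    and per-fold values.
    """
    if not positives:
        raise ValueError("empty holdout positives")
    params = params or DwpcParams()
    rng = np.random.default_rng(seed)
    pos = list(positives)
    neg = list(negatives)
    rng.shuffle(pos)
    rng.shuffle(neg)
    pos_folds = [pos[i::k_folds] for i in range(k_folds)]
    neg_folds = [neg[i::k_folds] for i in range(k_folds)]

    # features for training rows: own treats edge always masked
    def featurise(pairs, labels, extra):
        return build_features(
            graph,
            pairs,
            metapaths,
            params,
            labels=labels,
            treat_relation=treat_relation,
            extra_masked_edges=extra,
        )

    per_fold = []
    for k in range(k_folds):
        test_pos, test_neg = pos_folds[k], neg_folds[k]
        if not test_pos or not test_neg:
            continue
        train_pos = [p for i, f in enumerate(pos_folds) if i != k for p in f]
        train_neg = [p for i, f in enumerate(neg_folds) if i != k for p in f]
        fold_edges = [(d, treat_relation, z) for d, z in test_pos]
        train_feat = featurise(
            train_pos + train_neg,
            ["positive"] * len(train_pos) + ["negative"] * len(train_neg),
            fold_edges,
        )
        test_feat = featurise(
            test_pos + test_neg,
            ["positive"] * len(test_pos) + ["negative"] * len(test_neg),
            fold_edges,
        )
        model = train_model(train_feat, seed=seed + k)
        scores = model.scores(test_feat)
        y_true = (test_feat["label"] == "positive").to_numpy()
        auc = float(roc_auc_score(y_true, scores))
        f1 = float(f1_score(y_true, scores >= 0.5))
        per_fold.append({"fold": k, "auc": auc, "f1": f1})
    if not per_fold:
        raise ValueError("no evaluable fold (too few positives or negatives)")
    return {
        "auc": float(np.mean([f["auc"] for f in per_fold])),
        "f1": float(np.mean([f["f1"] for f in per_fold])),
        "auc_sd": float(np.std([f["auc"] for f in per_fold])),
        "f1_sd": float(np.std([f["f1"] for f in per_fold])),
        "per_fold": per_fold,
    }


def predict_treatments(
    model: TreatmentModel,
    graph: HetGraph,
    disease: str,
    candidate_drugs: Sequence[str] | None = None,
    metapaths: Sequence[Metapath] | None = None,
    params: DwpcParams | None = None,
    treat_relation: str = TREATS,
) -> pd.DataFrame:
    """Rank candidate drugs for one disease by model score.

    Candidates default to every DRUG node; pairs are featurised with their
    own treats edge masked so known treatments are scored on independent
    evidence. Drugs whose feature row is all zero are kept but flagged
    ``disconnected-features``. Output is sorted by descending score, ties
    by drug id.
    """
    if disease not in graph.nodes:
        raise ValueError(f"disease {disease!r} absent from graph")
    if metapaths is None:
        raise ValueError("metapaths must be supplied")
    drugs = list(candidate_drugs) if candidate_drugs else graph.nodes_of_type("DRUG")
    pairs = [(d, disease) for d in drugs]
    feats = build_features(
        graph, pairs, metapaths, params, treat_relation=treat_relation
    )
    scores = model.scores(feats)
    zero_row = (feats[model.feature_names].to_numpy() == 0).all(axis=1)
    out = pd.DataFrame(
        {
            "drug_id": drugs,
            "score": scores,
            "flag": np.where(zero_row, "disconnected-features", ""),
        }
    )
    return out.sort_values(
        ["score", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O: TSV edge list `source_id  source_type  relation  target_id  target_type`


def load_hetgraph_tsv(path: str | Path) -> HetGraph:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["source_id", "source_type", "relation", "target_id", "target_type"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"edge list missing columns {missing}")
    nodes: dict[str, str] = {}
    for _, row in table.iterrows():
        for node, ntype in ((row.source_id, row.source_type), (row.target_id, row.target_type)):
            if nodes.get(node, ntype) != ntype:
                raise ValueError(f"node {node!r} declared with conflicting types")
            nodes[node] = ntype
    edges = [(r.source_id, r.relation, r.target_id) for r in table.itertuples()]
    return HetGraph(nodes, edges)


def write_hetgraph_tsv(graph: HetGraph, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source_id": s,
                "source_type": graph.nodes[s],
                "relation": rel,
                "target_id": t,
                "target_type": graph.nodes[t],
            }
            for s, rel, t in sorted(graph.edges)
        ]
    ).to_csv(path, sep="\t", index=False)
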
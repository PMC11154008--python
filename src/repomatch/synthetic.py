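"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of a :class:`SimulationSpec`: the same
spec yields byte-identical outputs. The generators emulate, at desk scale,
the four kinds of real input the pipeline consumes:

* a differential-expression table with planted up/down effects whose
  p-values come from an actual two-group t-model (so BH behaves
  realistically);
* a drug-signature library in which designated therapeutic drugs *reverse*
  the disease signature — with per-gene probability ρ (the reversal
  strength) disease up-genes are pushed to the bottom of the drug's gene
  ranking and down-genes to the top — while background drugs are random
  permutations;
* a typed 8-node-type hetnet in which true treatment pairs are planted by
  giving drug and disease shared GENE neighbours, so path-count features
  (not the treat edge itself) carry the signal;
* a multiscale interactome with one planted drug→protein→function→protein→
  disease mechanism path whose interior is connected to both endpoints.

Reversal planting operates on ranks rather than expression values because
the matching pipeline only ever consumes rankings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dgem import Condition, DrugSignature, SignatureLibrary, write_library
from .hetnet import HetGraph, write_hetgraph_tsv
from .msi import build_msi_graph, write_msi_tsv
from .pathways import GeneSetCollection, write_gmt
from .signatures import DiseaseSignature

__all__ = [
    "SimulationSpec",
    "generate_disease_table",
    "generate_signature_library",
    "generate_hetnet",
    "generate_msi_graph",
    "generate_pathway_collection",
    "simulate_all",
]

_DEFAULT_HETNET_NODES = {
    "DRUG": 60,
    "DISEASE": 20,
    "GENE": 220,
    "PATHWAY": 60,
    "PHENOTYPE": 40,
    "TISSUE": 40,
    "VARIANT": 40,
    "COMPOUND_CLASS": 20,
}


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with the defaults used throughout.

    ``reversal_strength`` is ρ: the per-gene probability that a planted
    therapeutic drug displaces a disease gene to the extreme of its
    ranking. ``up_action`` / ``down_action`` control what a planted drug
    does to each directed gene set: ``reverse`` (therapeutic direction),
    ``mimic`` (same direction as the disease) or ``none``.
    """

    seed: int = 0
    # disease differential-expression table
    n_genes: int = 2000
    n_planted_up: int = 300
    n_planted_down: int = 300
    effect_mean: float = 3.0
    effect_sd: float = 0.5
    noise_scale: float = 1.0
    per_group_n: int = 10
    contrast_id: str = "disease_vs_normal"
    # drug-signature library
    n_drugs: int = 50
    conditions_per_drug: int = 3
    n_planted_drugs: int = 5
    reversal_strength: float = 0.8
    rank_noise: float = 0.05
    up_action: str = "reverse"
    down_action: str = "reverse"
    # hetnet
    hetnet_nodes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_HETNET_NODES)
    )
    treat_edge_rate: float = 0.05
    shared_genes_per_treatment: int = 3
    holdout_fraction: float = 0.25
    background_targets_per_drug: int = 3
    background_assoc_per_disease: int = 5
    # multiscale interactome
    msi_n_drugs: int = 6
    msi_n_diseases: int = 3
    msi_n_proteins: int = 80
    msi_n_functions: int = 40
    planted_path_length: int = 4
    # pathway collection
    n_pathways: int = 50

    def __post_init__(self) -> None:
        counts = [
            self.n_genes,
            self.n_planted_up,
            self.n_planted_down,
            self.per_group_n,
            self.n_drugs,
            self.conditions_per_drug,
            self.n_planted_drugs,
            self.msi_n_drugs,
            self.msi_n_diseases,
            self.msi_n_proteins,
            self.msi_n_functions,
            self.n_pathways,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0 <= self.reversal_strength <= 1:
            raise ValueError("reversal_strength must lie in [0, 1]")
        if self.planted_path_length < 2:
            raise ValueError("planted_path_length must be >= 2")
        for action in (self.up_action, self.down_action):
            if action not in ("reverse", "mimic", "none"):
                raise ValueError(f"unknown planting action {action!r}")

    # deterministic per-generator random streams
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug_{i:03d}" for i in range(self.n_drugs)]

    @property
    def planted_drug_ids(self) -> list[str]:
        return self.drug_ids[: self.n_planted_drugs]


def generate_disease_table(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Gene table with planted effects and the planted membership.

    Per-gene log fold change is the planted effect observed through a
    two-group t-model (``per_group_n`` samples per arm, noise SD
    ``noise_scale``); p-values come from the same simulated samples. With
    zero noise the observed effects are exact and planted genes carry
    p = 0.
    """
    rng = spec._rng(0)
    genes = spec.gene_ids
    planted = rng.choice(
        spec.n_genes, size=spec.n_planted_up + spec.n_planted_down, replace=False
    )
    up_idx = planted[: spec.n_planted_up]
    down_idx = planted[spec.n_planted_up:]
    effects = np.zeros(spec.n_genes)
    effects[up_idx] = np.abs(
        rng.normal(spec.effect_mean, spec.effect_sd, spec.n_planted_up)
    )
    effects[down_idx] = -np.abs(
        rng.normal(spec.effect_mean, spec.effect_sd, spec.n_planted_down)
    )
    if spec.noise_scale == 0:
        log_fc = effects
        p = np.where(effects != 0.0, 0.0, 1.0)
    else:
        control = rng.normal(0.0, spec.noise_scale, (spec.n_genes, spec.per_group_n))
        case = effects[:, None] + rng.normal(
            0.0, spec.noise_scale, (spec.n_genes, spec.per_group_n)
        )
        log_fc = case.mean(axis=1) - control.mean(axis=1)
        _, p = stats.ttest_ind(case, control, axis=1)
    table = pd.DataFrame(
        {"gene_id": genes, "log_fc": log_fc, "p_value": np.clip(p, 0.0, 1.0)}
    )
    table.attrs["contrast_id"] = spec.contrast_id
    membership = {
        "up": sorted(genes[i] for i in up_idx),
        "down": sorted(genes[i] for i in down_idx),
    }
    return table, membership


def _planted_scores(
    rng: np.random.Generator,
    scores: np.ndarray,
    idx: np.ndarray,
    rho: float,
    rank_noise: float,
    to_top: bool,
) -> None:
    """Displace a Bernoulli(ρ) subset of ``idx`` toward a ranking extreme."""
    hit = idx[rng.random(len(idx)) < rho]
    if len(hit) == 0:
        return
    if rank_noise == 0:
        # strictly beyond the background score range: an exact extreme block
        block = rng.random(len(hit))
        scores[hit] = (1.0 + block) if to_top else (-block)
    else:
        lo, hi = (1.0 - rank_noise, 1.0) if to_top else (0.0, rank_noise)
        scores[hit] = rng.uniform(lo, hi, len(hit))


def generate_signature_library(
    spec: SimulationSpec, disease_signature: DiseaseSignature
) -> SignatureLibrary:
    """Drug-signature library with planted signature-reversing drugs.

    Background drugs receive independent random rankings of the gene
    universe. Planted therapeutic drugs displace the disease signature's
    genes according to ``up_action``/``down_action`` (default: full
    reversal — up-genes to the bottom of the ranking, down-genes to the
    top), independently per condition, each gene moved with probability ρ.
    """
    rng = spec._rng(1)
    genes = np.array(spec.gene_ids)
    order_index = {g: i for i, g in enumerate(genes)}
    planted = set(spec.planted_drug_ids)
    if disease_signature.config.mode == "split":
        up_list = disease_signature.up_genes
        down_list = disease_signature.down_genes
    else:
        up_list = [
            g for g in disease_signature.up_genes
            if disease_signature.directions.get(g) == "up"
        ]
        down_list = [
            g for g in disease_signature.up_genes
            if disease_signature.directions.get(g) == "down"
        ]
    up_idx = np.array([order_index[g] for g in up_list if g in order_index], int)
    down_idx = np.array([order_index[g] for g in down_list if g in order_index], int)

    concentrations = [0.1 * 10**i for i in range(spec.conditions_per_drug)]
    signatures = []
    for drug_id in spec.drug_ids:
        for conc in concentrations:
            scores = rng.random(spec.n_genes)
            if drug_id in planted:
                rho = spec.reversal_strength
                if spec.up_action == "reverse":
                    _planted_scores(rng, scores, up_idx, rho, spec.rank_noise, False)
                elif spec.up_action == "mimic":
                    _planted_scores(rng, scores, up_idx, rho, spec.rank_noise, True)
                if spec.down_action == "reverse":
                    _planted_scores(rng, scores, down_idx, rho, spec.rank_noise, True)
                elif spec.down_action == "mimic":
                    _planted_scores(rng, scores, down_idx, rho, spec.rank_noise, False)
            order = np.argsort(-scores, kind="stable")
            ranking = genes[order].tolist()
            cond = Condition("cellA", float(f"{conc:.4g}"), "uM", "r1")
            signatures.append(DrugSignature(drug_id, cond, ranking))
    return SignatureLibrary(signatures)


def generate_hetnet(
    spec: SimulationSpec,
) -> tuple[HetGraph, pd.DataFrame]:
    """Typed hetnet with planted treatment pairs explained by shared genes.

    Each true (drug, disease) pair receives ``shared_genes_per_treatment``
    dedicated GENE neighbours (drug–targets–gene and gene–assoc–disease
    edges), so the DRUG–targets–GENE–assoc–DISEASE metapath is informative.
    A ``holdout_fraction`` of true pairs carry no treats edge in the graph;
    the returned label table marks every true pair ``train`` or
    ``holdout``.
    """
    rng = spec._rng(2)
    sizes = dict(spec.hetnet_nodes)
    for required in ("DRUG", "DISEASE", "GENE"):
        if sizes.get(required, 0) < 1:
            raise ValueError(f"hetnet requires at least one {required} node")
    prefix = {
        "DRUG": "drug",
        "DISEASE": "disease",
        "GENE": "gene",
        "PATHWAY": "pw",
        "PHENOTYPE": "ph",
        "TISSUE": "ts",
        "VARIANT": "var",
        "COMPOUND_CLASS": "cc",
    }
    ids: dict[str, list[str]] = {}
    nodes: dict[str, str] = {}
    for ntype, count in sizes.items():
        pre = prefix.get(ntype, ntype.lower())
        ids[ntype] = [f"{pre}_{i:03d}" for i in range(count)]
        nodes.update({n: ntype for n in ids[ntype]})

    edges: list[tuple[str, str, str]] = []

    def pick(pool: list[str], n: int) -> list[str]:
        n = min(n, len(pool))
        return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]

    for drug in ids["DRUG"]:
        for gene in pick(ids["GENE"], spec.background_targets_per_drug):
            edges.append((drug, "targets", gene))
        if ids.get("COMPOUND_CLASS"):
            edges.append((drug, "class_of", pick(ids["COMPOUND_CLASS"], 1)[0]))
    for disease in ids["DISEASE"]:
        for gene in pick(ids["GENE"], spec.background_assoc_per_disease):
            edges.append((disease, "assoc", gene))
        for ph in pick(ids.get("PHENOTYPE", []), 2):
            edges.append((disease, "presents", ph))
    for gene in ids["GENE"]:
        if ids.get("PATHWAY"):
            edges.append((gene, "member", pick(ids["PATHWAY"], 1)[0]))
        if ids.get("TISSUE"):
            edges.append((gene, "expressed", pick(ids["TISSUE"], 1)[0]))
    for var in ids.get("VARIANT", []):
        edges.append((var, "variant_in", pick(ids["GENE"], 1)[0]))

    n_pairs = len(ids["DRUG"]) * len(ids["DISEASE"])
    n_pos = int(round(spec.treat_edge_rate * n_pairs))
    all_pairs = [(d, z) for d in ids["DRUG"] for z in ids["DISEASE"]]
    pos_idx = rng.choice(len(all_pairs), size=n_pos, replace=False)
    positives = [all_pairs[i] for i in sorted(pos_idx)]
    n_holdout = int(round(spec.holdout_fraction * n_pos))
    holdout_pick = set(
        rng.choice(len(positives), size=n_holdout, replace=False).tolist()
    )
    labels = []
    for i, (drug, disease) in enumerate(positives):
        for gene in pick(ids["GENE"], spec.shared_genes_per_treatment):
            edges.append((drug, "targets", gene))
            edges.append((disease, "assoc", gene))
        split = "holdout" if i in holdout_pick else "train"
        if split == "train":
            edges.append((drug, "treats", disease))
        labels.append({"drug": drug, "disease": disease, "split": split})
    graph = HetGraph(nodes, edges, node_types=set(sizes))
    return graph, pd.DataFrame(labels)


def generate_msi_graph(
    spec: SimulationSpec,
) -> tuple[nx.Graph, list[str]]:
    """Interactome with one planted drug→…→disease mechanism path.

    The planted path for length L is drug – protein – (L−3 functions) –
    protein – disease (a single protein bridge for L = 2, two proteins for
    L = 3). Shortcut drug/disease edges to the far/near bridge proteins
    give the interior elevated visitation in *both* diffusion profiles,
    which is what distinguishes mechanism nodes from start-adjacent noise.
    """
    rng = spec._rng(3)
    drugs = [f"msidrug_{i:02d}" for i in range(spec.msi_n_drugs)]
    diseases = [f"msidisease_{i:02d}" for i in range(spec.msi_n_diseases)]
    proteins = [f"prot_{i:03d}" for i in range(spec.msi_n_proteins)]
    functions = [f"func_{i:03d}" for i in range(spec.msi_n_functions)]
    node_types: dict[str, str] = {}
    node_types.update({n: "drug" for n in drugs})
    node_types.update({n: "disease" for n in diseases})
    node_types.update({n: "protein" for n in proteins})
    node_types.update({n: "biological_function" for n in functions})

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    # connected protein backbone: random spanning tree plus extra PPI edges
    for i in range(1, len(proteins)):
        add(proteins[i], proteins[int(rng.integers(0, i))])
    for _ in range(len(proteins) // 2):
        a, b = rng.choice(len(proteins), 2, replace=False)
        add(proteins[a], proteins[b])
    # function hierarchy tree, each function anchored to a protein
    for i in range(1, len(functions)):
        add(functions[i], functions[int(rng.integers(0, i))])
    for fn in functions:
        add(fn, proteins[int(rng.integers(0, len(proteins)))])
    for drug in drugs:
        for i in rng.choice(len(proteins), 2, replace=False):
            add(drug, proteins[i])
    for disease in diseases:
        for i in rng.choice(len(proteins), 3, replace=False):
            add(disease, proteins[i])

    # planted mechanism path
    drug, disease = drugs[0], diseases[0]
    length = spec.planted_path_length
    if length == 2:
        interior = ["prot_planted_a"]
        node_types["prot_planted_a"] = "protein"
    elif length == 3:
        interior = ["prot_planted_a", "prot_planted_b"]
        node_types["prot_planted_a"] = "protein"
        node_types["prot_planted_b"] = "protein"
    else:
        interior = (
            ["prot_planted_a"]
            + [f"func_planted_{i}" for i in range(length - 3)]
            + ["prot_planted_b"]
        )
        node_types["prot_planted_a"] = "protein"
        node_types["prot_planted_b"] = "protein"
        for i in range(length - 3):
            node_types[f"func_planted_{i}"] = "biological_function"
    path = [drug, *interior, disease]
    for a, b in zip(path, path[1:]):
        add(a, b)
    # elevated connectivity: both endpoints touch both bridge proteins
    add(drug, interior[-1])
    add(disease, interior[0])

    graph = build_msi_graph(node_types, sorted(edges))
    return graph, path


def generate_pathway_collection(
    spec: SimulationSpec, planted_genes: list[str] | None = None
) -> GeneSetCollection:
    """Random pathway collection over the gene universe, plus one planted
    pathway drawn from the disease's planted genes (if given)."""
    rng = spec._rng(4)
    genes = spec.gene_ids
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(spec.n_pathways):
        size = int(rng.integers(20, 80))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        sets[f"PW{i:04d}"] = (
            f"random pathway {i}",
            frozenset(genes[j] for j in members),
        )
    if planted_genes:
        size = min(40, len(planted_genes))
        members = rng.choice(len(planted_genes), size=size, replace=False)
        sets["PW_PLANTED"] = (
            "planted disease pathway",
            frozenset(planted_genes[j] for j in members),
        )
    return GeneSetCollection("synthetic_pathways", sets)


def simulate_all(spec: SimulationSpec, out_dir: str | Path) -> dict:
    """Write every input format the other modules read, plus ground truth.

    Emits the disease gene table (TSV), the signature library (ranks +
    metadata TSVs), the hetnet edge list and treatment labels, the
    interactome edge list, a GMT pathway collection, and a JSON manifest of
    the planted ground truth. Returns the manifest.
    """
    from .signatures import SignatureConfig, build_disease_signature

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, membership = generate_disease_table(spec)
    table.to_csv(out / "disease_table.tsv", sep="\t", index=False)

    signature = build_disease_signature(
        table, SignatureConfig("split"), contrast_id=spec.contrast_id
    )
    library = generate_signature_library(spec, signature)
    write_library(library, out / "library")

    hetgraph, labels = generate_hetnet(spec)
    write_hetgraph_tsv(hetgraph, out / "hetnet_edges.tsv")
    labels.to_csv(out / "hetnet_labels.tsv", sep="\t", index=False)

    msi_graph, planted_path = generate_msi_graph(spec)
    write_msi_tsv(msi_graph, out / "msi_edges.tsv")

    collection = generate_pathway_collection(
        spec, membership["up"] + membership["down"]
    )
    write_gmt(collection, out / "pathways.gmt")

    manifest = {
        "spec": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(spec).items()
        },
        "planted_genes": membership,
        "planted_drugs": spec.planted_drug_ids,
        "planted_treatments": labels.to_dict(orient="records"),
        "planted_msi_path": planted_path,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
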
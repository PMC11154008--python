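"""End-to-end discovery flow: signatures → DGEM → hetnet → combine → explain.

``run_discovery`` executes the full synthetic study: it generates (or
loads) every input, selects the disease-signature configuration with the
control drug, ranks the library by connectivity, evaluates and applies the
hetnet treatment classifier, joins the two prediction lists into one
combined candidate table, runs consensus pathway enrichment for the top
reversal drugs, and extracts the interactome mechanism subgraph for the
planted drug–disease pair. Every output is a TSV or JSON file and a run
manifest records seeds, configuration and the SHA-256 of every file, so a
rerun with the same configuration is byte-identical.

The combined table stops at computed ranks: downstream shortlisting
against clinical and regulatory considerations is a manual step outside
this package's scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dgem, hetnet, msi, pathways, signatures, synthetic

__all__ = ["PipelineConfig", "PipelineError", "run_discovery", "combine_predictions"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""


@dataclass
class PipelineConfig:
    """Configuration of one discovery run."""

    out_dir: str | Path = "discovery_run"
    spec: synthetic.SimulationSpec = field(
        default_factory=synthetic.SimulationSpec
    )
    data_dir: str | Path | None = None  # pre-generated inputs; None → simulate
    configs: tuple[signatures.SignatureConfig, ...] = (
        signatures.SignatureConfig("split"),
        signatures.SignatureConfig("combined"),
    )
    control_drugs: tuple[str, ...] | None = None  # None → first planted drug
    significance_cutoff: float = 0.05
    overlap_threshold: float = 0.5
    overlap_cap: int = 100
    n_pathway_drugs: int = 2
    dwpc_params: hetnet.DwpcParams = field(default_factory=hetnet.DwpcParams)
    msi_params: msi.MSIParams = field(default_factory=msi.MSIParams)
    k_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.data_dir is not None:
            data = Path(self.data_dir)
            required = [
                "disease_table.tsv",
                "library/ranks.tsv",
                "library/metadata.tsv",
                "hetnet_edges.tsv",
                "hetnet_labels.tsv",
                "msi_edges.tsv",
                "pathways.gmt",
                "ground_truth.json",
            ]
            missing = [f for f in required if not (data / f).exists()]
            if missing:
                raise PipelineError(
                    f"stage validate: missing input files under {data}: {missing}"
                )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rank_table(frame: pd.DataFrame, score_col: str, absolute: bool) -> pd.Series:
    key = frame[score_col].abs() if absolute else frame[score_col]
    order = (-key).rank(method="first")
    return order.astype(int)


def combine_predictions(
    dgem_ranks: pd.DataFrame, dwpc_ranks: pd.DataFrame
) -> pd.DataFrame:
    """Outer join of the two prediction lists keyed by ``drug_id``.

    Adds 1-based per-module rank columns (DGEM by absolute condensed
    score, hetnet by model score), a ``combined_rank`` key equal to the
    mean of available ranks, and a ``modules`` flag marking drugs present
    in only one list. Sorted by the combined key, ties by drug id.
    """
    rank_col = (
        "condensed_raw" if "condensed_raw" in dgem_ranks.columns else "condensed_score"
    )
    left = dgem_ranks[["drug_id", "condensed_score", rank_col]].copy()
    left = left.loc[:, ~left.columns.duplicated()]
    left["dgem_rank"] = _rank_table(left, rank_col, absolute=True)
    left = left[["drug_id", "condensed_score", "dgem_rank"]]
    right = dwpc_ranks[["drug_id", "score"]].rename(columns={"score": "dwpc_score"})
    right = right.copy()
    right["dwpc_rank"] = _rank_table(right, "dwpc_score", absolute=False)
    merged = left.merge(right, on="drug_id", how="outer")
    both = merged["dgem_rank"].notna() & merged["dwpc_rank"].notna()
    merged["modules"] = np.select(
        [both, merged["dgem_rank"].notna()], ["both", "dgem_only"], "dwpc_only"
    )
    merged["combined_rank"] = merged[["dgem_rank", "dwpc_rank"]].mean(axis=1)
    return merged.sort_values(
        ["combined_rank", "drug_id"], kind="mergesort"
    ).reset_index(drop=True)


def run_discovery(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.spec
    manifest: dict = {
        "seed": config.seed,
        "spec_seed": spec.seed,
        "stages": [],
        "files": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    def run_stage(stage: str, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {stage}: {exc}") from exc

    # -- stage 1: inputs -----------------------------------------------------
    def stage_inputs():
        if config.data_dir is None:
            data = out / "data"
            synthetic.simulate_all(spec, data)
        else:
            data = Path(config.data_dir)
        table = signatures.read_gene_table(
            data / "disease_table.tsv", contrast_id=spec.contrast_id
        )
        library = dgem.load_library(data / "library")
        graph = hetnet.load_hetgraph_tsv(data / "hetnet_edges.tsv")
        labels = pd.read_csv(data / "hetnet_labels.tsv", sep="\t", dtype=str)
        msi_graph = msi.load_msi_tsv(data / "msi_edges.tsv")
        collection = pathways.read_gmt(data / "pathways.gmt")
        truth = json.loads((data / "ground_truth.json").read_text())
        return data, table, library, graph, labels, msi_graph, collection, truth

    data, table, library, graph, labels, msi_graph, collection, truth = run_stage(
        "simulate", stage_inputs
    )
    if config.data_dir is None:
        record("simulate", *sorted(p for p in (out / "data").rglob("*") if p.is_file()))
    else:
        manifest["stages"].append("load")

    # -- stage 2: signature configuration selection --------------------------
    def stage_signatures():
        controls = list(config.control_drugs or spec.planted_drug_ids[:1])
        choice = dgem.select_configuration(
            table,
            list(config.configs),
            controls,
            library,
            config.significance_cutoff,
            contrast_id=spec.contrast_id,
        )
        sig = signatures.build_disease_signature(
            table,
            choice.chosen_config,
            config.significance_cutoff,
            contrast_id=spec.contrast_id,
        )
        dgem.write_config_choice_json(choice, out / "config_choice.json")
        signatures.write_signature_json(sig, out / "signature.json")
        signatures.write_signature_tsv(sig, out / "signature.tsv")
        return choice, sig

    choice, signature = run_stage("signatures", stage_signatures)
    record("signatures", out / "config_choice.json", out / "signature.json",
           out / "signature.tsv")

    # -- stage 3: DGEM ranking ------------------------------------------------
    def stage_dgem():
        ranks = dgem.rank_drugs(signature, library)
        dgem.write_ranking_tsv(ranks, out / "dgem_ranking.tsv")
        return ranks

    ranks = run_stage("dgem", stage_dgem)
    record("dgem", out / "dgem_ranking.tsv")

    # -- stage 4: hetnet prediction -------------------------------------------
    def stage_hetnet():
        metapaths = hetnet.enumerate_metapaths(
            graph.metaedges(), config.dwpc_params.max_metapath_length
        )
        train_pos = [
            (r.drug, r.disease)
            for r in labels.itertuples()
            if r.split == "train"
        ]
        holdout_pos = [
            (r.drug, r.disease)
            for r in labels.itertuples()
            if r.split == "holdout"
        ]
        rng = np.random.default_rng(config.seed)
        negatives = hetnet.sample_negative_pairs(graph, train_pos, 4.0, rng)
        metrics = hetnet.evaluate_holdout(
            graph,
            train_pos,
            negatives,
            metapaths,
            config.dwpc_params,
            k_folds=config.k_folds,
            seed=config.seed,
        )
        features = hetnet.build_features(
            graph,
            train_pos + negatives,
            metapaths,
            config.dwpc_params,
            labels=["positive"] * len(train_pos) + ["negative"] * len(negatives),
        )
        model = hetnet.train_model(features, seed=config.seed)
        # predict for the disease with the most held-out true treatments
        focal_counts: dict[str, int] = {}
        for _, dis in holdout_pos:
            focal_counts[dis] = focal_counts.get(dis, 0) + 1
        focal = min(focal_counts or {d: 0 for _, d in train_pos},
                    key=lambda d: (-focal_counts.get(d, 0), d))
        predictions = hetnet.predict_treatments(
            model, graph, focal, metapaths=metapaths, params=config.dwpc_params
        )
        (out / "hetnet_metrics.json").write_text(
            json.dumps(metrics, indent=1, sort_keys=True) + "\n"
        )
        model.to_json(out / "hetnet_model.json")
        predictions.to_csv(out / "hetnet_predictions.tsv", sep="\t", index=False)
        return metrics, model, focal, predictions

    metrics, model, focal_disease, predictions = run_stage("hetnet", stage_hetnet)
    record("hetnet", out / "hetnet_metrics.json", out / "hetnet_model.json",
           out / "hetnet_predictions.tsv")
    manifest["focal_disease"] = focal_disease

    # -- stage 5: combined candidate table ------------------------------------
    def stage_combine():
        dgem_table = pd.read_csv(out / "dgem_ranking.tsv", sep="\t")
        combined = combine_predictions(dgem_table, predictions)
        combined.to_csv(out / "combined_candidates.tsv", sep="\t", index=False)
        return combined

    combined = run_stage("combine", stage_combine)
    record("combine", out / "combined_candidates.tsv")

    # -- stage 6: consensus pathway enrichment --------------------------------
    def stage_pathways():
        universe = frozenset(library.gene_universe)
        per_contrast: dict[str, list[pathways.EnrichmentResult]] = {}
        top_drugs = [r.drug_id for r in ranks[: config.n_pathway_drugs]]
        for drug_id in top_drugs:
            scored = dgem.scale_scores(
                [
                    dgem.connectivity_score(signature, sig)
                    for sig in library.signatures
                ]
            )
            per_condition = []
            for sig, res in zip(library.signatures, scored):
                if sig.drug_id != drug_id:
                    continue
                genes = pathways.leading_edge_genes(
                    signature, sig, cap=config.overlap_cap
                )
                per_condition.append((sig.condition, res.scaled_score, genes))
            overlap = pathways.amalgamate_signatures(
                drug_id,
                per_condition,
                threshold=config.overlap_threshold,
                cap=config.overlap_cap,
                contrast_id=signature.contrast_id,
            )
            if not overlap.genes:
                continue
            results = pathways.enrich(overlap, collection, universe)
            per_contrast[f"{drug_id}:{signature.contrast_id}"] = results
            pathways.write_enrichment_tsv(
                results, out / f"enrichment_{drug_id}.tsv"
            )
        consensus = pathways.consensus_rank(per_contrast) if per_contrast else (
            pd.DataFrame(columns=["pathway_id", "mean_rank", "n_contrasts_present"])
        )
        consensus.to_csv(out / "consensus_pathways.tsv", sep="\t", index=False)
        return sorted(per_contrast)

    enriched_keys = run_stage("pathways", stage_pathways)
    record("pathways", out / "consensus_pathways.tsv",
           *sorted(out.glob("enrichment_*.tsv")))

    # -- stage 7: interactome mechanism ---------------------------------------
    def stage_msi():
        planted_path = truth["planted_msi_path"]
        drug, disease = planted_path[0], planted_path[-1]
        drug_profile = msi.diffusion_profile(msi_graph, config.msi_params, drug)
        disease_profile = msi.diffusion_profile(
            msi_graph, config.msi_params, disease
        )
        top = msi.rank_relevant_nodes(
            drug_profile, disease_profile, msi_graph, k=config.msi_params.k
        )
        sub = msi.extract_mechanism_subgraph(msi_graph, drug, disease, top)
        msi.write_profile_tsv(drug_profile, msi_graph, out / "msi_drug_profile.tsv")
        msi.write_profile_tsv(
            disease_profile, msi_graph, out / "msi_disease_profile.tsv"
        )
        (out / "mechanism_subgraph.json").write_text(
            json.dumps(msi.subgraph_to_json(sub), indent=1, sort_keys=True) + "\n"
        )
        (out / "mechanism_subgraph.dot").write_text(
            msi.subgraph_to_dot(sub, msi_graph) + "\n"
        )
        return top, sub

    top_nodes, subgraph = run_stage("msi", stage_msi)
    record("msi", out / "msi_drug_profile.tsv", out / "msi_disease_profile.tsv",
           out / "mechanism_subgraph.json", out / "mechanism_subgraph.dot")

    manifest["hetnet_auc"] = metrics["auc"]
    manifest["hetnet_f1"] = metrics["f1"]
    manifest["enrichment_runs"] = enriched_keys
    manifest["msi_top_nodes"] = top_nodes
    manifest["n_mechanism_paths"] = len(subgraph.paths)
    manifest["chosen_config"] = choice.chosen_config.label
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
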
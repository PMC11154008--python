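"""Disease gene expression matching (DGEM).

Connectivity mapping scores a disease signature against a library of drug
signatures — full gene rankings per drug × experimental condition, rank 1
being the gene most up-regulated by treatment. The score is built from a
weighted Kolmogorov–Smirnov enrichment statistic: for a tag set of size
``t`` whose members sit at ascending ranks ``V(1..t)`` within a universe of
``n`` genes,

    a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t )
    ks = a  if a > b  else  −b

so tags concentrated at the top of the ranking score near +1 and tags at
the bottom near −1. In split mode the connectivity score is
``ks_up − ks_down`` when the two component statistics disagree in sign and
0 when they strictly share a sign; in combined mode the single tag list is
scored directly. Raw scores are then scaled per batch: positive scores by
the maximum positive, negative by the magnitude of the minimum negative,
bounding everything in [−1, 1]. A negative score means the drug *reverses*
the disease signature (up-genes pushed down, down-genes pushed up) — the
therapeutic direction.

DGEM adds configuration selection on top: each candidate signature
configuration is evaluated by how strongly a set of known-active control
drugs (the original study used metformin alone) connects to the disease,
and the configuration with the highest control score wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import DiseaseSignature, SignatureConfig, build_disease_signature

__all__ = [
    "Condition",
    "DrugSignature",
    "SignatureLibrary",
    "ConnectivityResult",
    "DgemConfigChoice",
    "DrugRank",
    "MatchingError",
    "ks_enrichment",
    "connectivity_score",
    "scale_scores",
    "rank_drugs",
    "select_configuration",
    "load_library",
    "write_ranking_tsv",
]


class MatchingError(ValueError):
    """Raised when a signature cannot be matched against a library."""


@dataclass(frozen=True, order=True)
class Condition:
    """One experimental condition of a drug signature."""

    cell_context: str = "cell"
    concentration: float = 10.0
    unit: str = "uM"
    replicate: str = "r1"

    @property
    def label(self) -> str:
        return f"{self.cell_context}:{self.concentration:g}{self.unit}:{self.replicate}"


@dataclass
class DrugSignature:
    """Full gene ranking induced by one drug under one condition.

    ``ranking`` is an ordered list over the library's entire gene universe;
    position 1 holds the gene most up-regulated by the treatment.
    """

    drug_id: str
    condition: Condition
    ranking: list[str]
    _rank_of: dict[str, int] = field(default_factory=dict, repr=False)

    def rank_of(self, gene: str) -> int:
        """1-based rank of ``gene`` in this signature."""
        if not self._rank_of:
            self._rank_of.update(
                {g: i + 1 for i, g in enumerate(self.ranking)}
            )
        return self._rank_of[gene]

    def ranks_of(self, genes: Iterable[str]) -> np.ndarray:
        if not self._rank_of:
            self.rank_of(self.ranking[0])
        return np.array(sorted(self._rank_of[g] for g in genes), dtype=float)


class SignatureLibrary:
    """A collection of drug signatures over a shared gene universe."""

    def __init__(self, signatures: Sequence[DrugSignature]):
        if not signatures:
            raise ValueError("empty signature library")
        universe = frozenset(signatures[0].ranking)
        for sig in signatures:
            if frozenset(sig.ranking) != universe or len(sig.ranking) != len(universe):
                raise ValueError(
                    f"signature {sig.drug_id}/{sig.condition.label} is not a "
                    "permutation of the library gene universe"
                )
        self.gene_universe: frozenset[str] = universe
        self.signatures: list[DrugSignature] = list(signatures)
        self._by_drug: dict[str, list[DrugSignature]] = {}
        for sig in signatures:
            self._by_drug.setdefault(sig.drug_id, []).append(sig)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self._by_drug)

    def for_drug(self, drug_id: str) -> list[DrugSignature]:
        return self._by_drug[drug_id]

    def __len__(self) -> int:
        return len(self.signatures)


@dataclass
class ConnectivityResult:
    """KS components and raw/scaled connectivity score for one pair."""

    drug_id: str
    condition: Condition
    ks_up: float
    ks_down: float
    raw_score: float
    scaled_score: float = 0.0


@dataclass
class DgemConfigChoice:
    """Outcome of control-drug configuration selection, with audit trail."""

    contrast_id: str
    chosen_config: SignatureConfig
    control_drug_ids: list[str]
    control_score_per_config: dict[str, float]


@dataclass
class DrugRank:
    """Per-drug condensation: the most extreme condition's scores.

    ``condensed_raw`` orders the ranking (scaled magnitudes are only
    comparable within a sign, raw magnitudes across the whole batch);
    ``condensed_score`` is the same condition's scaled score, the quantity
    downstream threshold filters consume.
    """

    drug_id: str
    condensed_score: float
    condensed_raw: float
    n_conditions: int
    best_condition: Condition


def ks_enrichment(tags: Iterable[str], ranking: Sequence[str] | DrugSignature) -> float:
    """Weighted KS enrichment of a tag set within a ranked gene list.

    Returns a value in (−1, 1]; positive when the tags crowd the top of the
    ranking, negative when they crowd the bottom.
    """
    if isinstance(ranking, DrugSignature):
        n = len(ranking.ranking)
        tag_set = set(tags)
        if not tag_set:
            raise MatchingError("empty tag set")
        try:
            v = ranking.ranks_of(tag_set)
        except KeyError as exc:
            raise MatchingError(f"tag {exc.args[0]!r} not in gene universe") from exc
    else:
        ranking = list(ranking)
        n = len(ranking)
        tag_set = set(tags)
        if not tag_set:
            raise MatchingError("empty tag set")
        pos = {g: i + 1 for i, g in enumerate(ranking)}
        if not tag_set <= pos.keys():
            missing = sorted(tag_set - pos.keys())[:3]
            raise MatchingError(f"tags not in gene universe: {missing}")
        v = np.array(sorted(pos[g] for g in tag_set), dtype=float)
    t = len(tag_set)
    if t >= n:
        raise MatchingError("tag set must be a strict subset of the universe")
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a if a > b else -b)


def connectivity_score(
    signature: DiseaseSignature, drug: DrugSignature
) -> ConnectivityResult:
    """Score one disease signature against one drug signature.

    Signature genes absent from the drug's gene universe are dropped before
    scoring; in split mode both directed lists must remain non-empty.
    """
    universe = set(drug.ranking)
    if signature.config.mode == "split":
        up = [g for g in signature.up_genes if g in universe]
        down = [g for g in signature.down_genes if g in universe]
        if not up or not down:
            raise MatchingError(
                f"signature {signature.contrast_id!r} vs drug {drug.drug_id!r}: "
                "a directed gene list is empty after universe intersection"
            )
        ks_up = ks_enrichment(up, drug)
        ks_down = ks_enrichment(down, drug)
        raw = 0.0 if ks_up * ks_down > 0 else ks_up - ks_down
        return ConnectivityResult(drug.drug_id, drug.condition, ks_up, ks_down, raw)
    combined = [g for g in signature.up_genes if g in universe]
    if not combined:
        raise MatchingError(
            f"signature {signature.contrast_id!r} has no gene in the universe "
            f"of drug {drug.drug_id!r}"
        )
    ks = ks_enrichment(combined, drug)
    return ConnectivityResult(drug.drug_id, drug.condition, ks, 0.0, ks)


def scale_scores(results: Sequence[ConnectivityResult]) -> list[ConnectivityResult]:
    """Scale raw scores into [−1, 1] across one batch of results.

    Positive raw scores are divided by the maximum positive raw score,
    negative by the magnitude of the most negative; zeros stay zero. The
    operation is idempotent.
    """
    if not results:
        raise ValueError("empty result list")
    raws = np.array([r.raw_score for r in results])
    pos_max = raws[raws > 0].max() if np.any(raws > 0) else 1.0
    neg_min = abs(raws[raws < 0].min()) if np.any(raws < 0) else 1.0
    out = []
    for r in results:
        if r.raw_score > 0:
            scaled = r.raw_score / pos_max
        elif r.raw_score < 0:
            scaled = r.raw_score / neg_min
        else:
            scaled = 0.0
        out.append(
            ConnectivityResult(
                r.drug_id, r.condition, r.ks_up, r.ks_down, r.raw_score, scaled
            )
        )
    return out


def score_library(
    signature: DiseaseSignature, library: SignatureLibrary
) -> list[ConnectivityResult]:
    """Connectivity of one disease signature against every library instance,
    scaled across the whole batch (per-contrast scaling)."""
    results = [connectivity_score(signature, drug) for drug in library.signatures]
    return scale_scores(results)


def _condense(results: Sequence[ConnectivityResult]) -> ConnectivityResult:
    # max |raw| with sign retained; deterministic tie-break by condition
    return max(
        results, key=lambda r: (abs(r.raw_score), r.condition)
    )


def rank_drugs(
    signature: DiseaseSignature, library: SignatureLibrary
) -> list[DrugRank]:
    """Condensed per-drug ranking of the whole library.

    Every condition of every drug is scored and scaled; each drug is then
    condensed to its single most extreme condition (sign retained) and
    drugs are ordered by descending absolute condensed raw score, ties
    broken by ``drug_id``.
    """
    scored = score_library(signature, library)
    per_drug: dict[str, list[ConnectivityResult]] = {}
    for res in scored:
        per_drug.setdefault(res.drug_id, []).append(res)
    ranks = []
    for drug_id in sorted(per_drug):
        best = _condense(per_drug[drug_id])
        ranks.append(
            DrugRank(
                drug_id,
                best.scaled_score,
                best.raw_score,
                len(per_drug[drug_id]),
                best.condition,
            )
        )
    ranks.sort(key=lambda r: (-abs(r.condensed_raw), r.drug_id))
    return ranks


def select_configuration(
    contrast: pd.DataFrame,
    configs: Sequence[SignatureConfig],
    control_drugs: Sequence[str],
    library: SignatureLibrary,
    significance_cutoff: float = 0.05,
    contrast_id: str | None = None,
) -> DgemConfigChoice:
    """Choose the signature configuration that best connects the controls.

    For each configuration the disease signature is built, the whole library
    is scored and scaled, each control drug is condensed to its most extreme
    scaled score, and control scores are aggregated by the mean of their
    magnitudes. The configuration with the highest aggregate wins; on an
    exact tie a split configuration is preferred, then input order.
    """
    if not configs:
        raise ValueError("empty configuration list")
    if not control_drugs:
        raise ValueError("no control drugs given")
    known = set(library.drug_ids)
    for drug in control_drugs:
        if drug not in known:
            raise MatchingError(f"control drug {drug!r} absent from library")
    cid = contrast_id or str(contrast.attrs.get("contrast_id", "contrast"))

    scores: dict[str, float] = {}
    best_key: tuple[float, int, int] | None = None
    chosen: SignatureConfig | None = None
    for order, config in enumerate(configs):
        sig = build_disease_signature(
            contrast, config, significance_cutoff, contrast_id=cid
        )
        scored = score_library(sig, library)
        per_control = []
        for drug in control_drugs:
            own = [r for r in scored if r.drug_id == drug]
            per_control.append(abs(_condense(own).scaled_score))
        scores[config.label] = float(np.mean(per_control))
        # higher score wins; ties prefer split mode, then earlier position
        key = (scores[config.label], 1 if config.mode == "split" else 0, -order)
        if best_key is None or key > best_key:
            best_key, chosen = key, config
    assert chosen is not None
    return DgemConfigChoice(cid, chosen, list(control_drugs), scores)


# ---------------------------------------------------------------------------
# I/O


def load_library(directory: str | Path) -> SignatureLibrary:
    """Load a signature library from a directory.

    Expects ``ranks.tsv`` — a wide TSV with a ``gene_id`` column and one
    column per signature instance holding that gene's 1-based rank — and
    ``metadata.tsv`` with columns ``instance``, ``drug_id``, ``cell_context``,
    ``concentration``, ``unit``, ``replicate``.
    """
    directory = Path(directory)
    ranks = pd.read_csv(directory / "ranks.tsv", sep="\t", dtype={"gene_id": str})
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", dtype=str)
    genes = ranks["gene_id"].tolist()
    signatures = []
    for row in meta.itertuples(index=False):
        order = np.argsort(ranks[row.instance].to_numpy(), kind="stable")
        ranking = [genes[i] for i in order]
        cond = Condition(
            row.cell_context, float(row.concentration), row.unit, row.replicate
        )
        signatures.append(DrugSignature(row.drug_id, cond, ranking))
    return SignatureLibrary(signatures)


def write_library(library: SignatureLibrary, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genes = sorted(library.gene_universe)
    data: dict[str, list] = {"gene_id": genes}
    meta_rows = []
    for i, sig in enumerate(library.signatures):
        name = f"inst_{i:04d}"
        data[name] = [sig.rank_of(g) for g in genes]
        meta_rows.append(
            {
                "instance": name,
                "drug_id": sig.drug_id,
                "cell_context": sig.condition.cell_context,
                "concentration": sig.condition.concentration,
                "unit": sig.condition.unit,
                "replicate": sig.condition.replicate,
            }
        )
    pd.DataFrame(data).to_csv(directory / "ranks.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(directory / "metadata.tsv", sep="\t", index=False)


def write_ranking_tsv(ranks: Sequence[DrugRank], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "condensed_score": r.condensed_score,
                "condensed_raw": r.condensed_raw,
                "n_conditions": r.n_conditions,
                "best_condition": r.best_condition.label,
            }
            for r in ranks
        ]
    ).to_csv(path, sep="\t", index=False)


def write_config_choice_json(choice: DgemConfigChoice, path: str | Path) -> None:
    payload = {
        "contrast_id": choice.contrast_id,
        "chosen_config": choice.chosen_config.label,
        "control_drug_ids": choice.control_drug_ids,
        "control_score_per_config": choice.control_score_per_config,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
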
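"""Overlap genes behind connectivity scores and consensus pathway enrichment.

The genes "driving" a drug–disease connectivity score are taken to be the
leading edge of the KS running statistic: for each tag set, the signature
genes at or before the position where the running deviation peaks. Leading
edges from the up- and down-gene sets are pooled, ordered by how extreme
their rank is in the drug signature, and capped (default 100 genes,
direction ignored). Gene lists from a drug's multiple concentrations are
amalgamated into one unified set, keeping only conditions whose scaled
connectivity score has magnitude >= 0.5.

Enrichment of the amalgamated set against a pathway collection (any GMT
file) uses the one-sided Fisher exact / hypergeometric tail test with BH
adjustment; consensus across disease contrasts is the mean per-contrast rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dgem import Condition, DrugSignature, connectivity_score
from .signatures import DiseaseSignature, adjust_pvalues_bh

__all__ = [
    "GeneSetCollection",
    "OverlapGeneSet",
    "EnrichmentResult",
    "leading_edge_genes",
    "amalgamate_signatures",
    "enrich",
    "consensus_rank",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named pathway collection: pathway_id -> (pathway_name, gene set)."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")


@dataclass
class OverlapGeneSet:
    """Unified overlap-gene list for one drug against one contrast."""

    drug_id: str
    contrast_id: str
    genes: list[str]
    source_conditions: list[tuple[Condition, float]] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    overlap_count: int
    p_value: float
    adj_p: float
    rank: int


def _leading_edge(tags: Sequence[str], drug: DrugSignature) -> list[str]:
    """Tags inside the leading edge of the KS running statistic.

    For a positive deviation these are the tags ranked at or before the
    argmax of ``j/t − V(j)/n``; for a negative deviation, the tags at or
    after the argmax of ``V(j)/n − (j−1)/t`` (the trailing block).
    """
    n = len(drug.ranking)
    ordered = sorted(tags, key=drug.rank_of)
    v = np.array([drug.rank_of(g) for g in ordered], dtype=float)
    t = len(ordered)
    j = np.arange(1, t + 1, dtype=float)
    a_run = j / t - v / n
    b_run = v / n - (j - 1) / t
    a, b = a_run.max(), b_run.max()
    if a > b:
        jstar = int(np.argmax(a_run))
        return ordered[: jstar + 1]
    jstar = int(np.argmax(b_run))
    return ordered[jstar:]


def _extremity(rank: int, n: int) -> int:
    return min(rank, n + 1 - rank)


def leading_edge_genes(
    signature: DiseaseSignature, drug: DrugSignature, cap: int = 100
) -> list[str]:
    """Signature genes that drive the connectivity score for one pair.

    Pools the KS leading edge of each tag set, orders genes by the
    extremity of their rank in the drug signature (most extreme first,
    ties by gene id) and truncates to ``cap``. A pair whose raw
    connectivity score is exactly zero yields an empty list with a warning.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    res = connectivity_score(signature, drug)
    if res.raw_score == 0.0:
        logger.warning(
            "pair %s / %s has zero connectivity score; no driving genes",
            signature.contrast_id,
            drug.drug_id,
        )
        return []
    universe = set(drug.ranking)
    pooled: set[str] = set()
    if signature.config.mode == "split":
        up = [g for g in signature.up_genes if g in universe]
        down = [g for g in signature.down_genes if g in universe]
        pooled.update(_leading_edge(up, drug))
        pooled.update(_leading_edge(down, drug))
    else:
        combined = [g for g in signature.up_genes if g in universe]
        pooled.update(_leading_edge(combined, drug))
    n = len(drug.ranking)
    ordered = sorted(pooled, key=lambda g: (_extremity(drug.rank_of(g), n), g))
    return ordered[:cap]


def amalgamate_signatures(
    drug_id: str,
    results: Sequence[tuple[Condition, float, Sequence[str]]],
    threshold: float = 0.5,
    cap: int = 100,
    contrast_id: str = "contrast",
) -> OverlapGeneSet:
    """Merge per-condition overlap gene lists into one unified set.

    Conditions with ``|score| < threshold`` are excluded (the comparison is
    inclusive at the threshold). Remaining ordered lists are merged by each
    gene's best position across contributing conditions, de-duplicated, and
    truncated to ``cap``. If nothing passes the filter an empty set is
    returned with a warning rather than an error.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    kept = [
        (cond, score, list(genes))
        for cond, score, genes in results
        if abs(score) >= threshold
    ]
    if not kept:
        logger.warning(
            "drug %s: no condition reaches |score| >= %.3g; empty overlap set",
            drug_id,
            threshold,
        )
        return OverlapGeneSet(drug_id, contrast_id, [], [])
    best_pos: dict[str, int] = {}
    for _, _, genes in kept:
        for pos, gene in enumerate(genes):
            if gene not in best_pos or pos < best_pos[gene]:
                best_pos[gene] = pos
    merged = sorted(best_pos, key=lambda g: (best_pos[g], g))[:cap]
    return OverlapGeneSet(
        drug_id, contrast_id, merged, [(c, s) for c, s, _ in kept]
    )


def enrich(
    query: OverlapGeneSet | Sequence[str],
    collection: GeneSetCollection,
    universe: set[str] | frozenset[str],
) -> list[EnrichmentResult]:
    """One-sided enrichment of a query gene set against a pathway collection.

    Per pathway (intersected with the background universe first) the
    hypergeometric upper-tail p-value of the observed overlap is computed,
    BH-adjusted across all tested pathways, and results are ranked by
    ascending p (ties by pathway id). Pathways with empty universe
    intersection are skipped with a log entry.
    """
    genes = list(query.genes) if isinstance(query, OverlapGeneSet) else list(query)
    qset = set(genes)
    if not qset:
        raise ValueError("empty query gene set")
    if not qset <= set(universe):
        missing = sorted(qset - set(universe))[:3]
        raise ValueError(f"query genes outside universe: {missing}")
    big_n = len(universe)
    rows = []
    for pid in sorted(collection.sets):
        pname, pgenes = collection.sets[pid]
        inter = pgenes & set(universe)
        if not inter:
            logger.info("pathway %s has no gene in the universe; skipped", pid)
            continue
        overlap = len(qset & inter)
        p = float(hypergeom.sf(overlap - 1, big_n, len(inter), len(qset)))
        rows.append((pid, pname, overlap, min(p, 1.0)))
    if not rows:
        return []
    adj = adjust_pvalues_bh([r[3] for r in rows])
    order = sorted(range(len(rows)), key=lambda i: (rows[i][3], rows[i][0]))
    results = []
    for rank, i in enumerate(order, start=1):
        pid, pname, overlap, p = rows[i]
        results.append(EnrichmentResult(pid, pname, overlap, p, float(adj[i]), rank))
    return results


def consensus_rank(
    per_contrast: Mapping[str, Sequence[EnrichmentResult]],
) -> pd.DataFrame:
    """Consensus pathway table across disease contrasts.

    Each pathway's mean rank is computed over the contrasts in which it was
    tested; rows are ordered by mean rank (ties by pathway id). Per-contrast
    rank columns are retained for plotting.
    """
    if not per_contrast:
        raise ValueError("at least one contrast required")
    contrasts = sorted(per_contrast)
    ranks: dict[str, dict[str, float]] = {}
    names: dict[str, str] = {}
    for cid in contrasts:
        for res in per_contrast[cid]:
            ranks.setdefault(res.pathway_id, {})[cid] = res.rank
            names[res.pathway_id] = res.pathway_name
    rows = []
    for pid in sorted(ranks):
        present = ranks[pid]
        row: dict[str, object] = {"pathway_id": pid, "pathway_name": names[pid]}
        for cid in contrasts:
            row[f"rank_{cid}"] = present.get(cid, np.nan)
        row["mean_rank"] = float(np.mean(list(present.values())))
        row["n_contrasts_present"] = len(present)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["mean_rank", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT I/O (name <TAB> description <TAB> gene1 <TAB> gene2 ...)


def read_gmt(path: str | Path, collection_name: str | None = None) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if pid in sets:
            raise ValueError(f"duplicate pathway id {pid!r} in GMT")
        sets[pid] = (desc or pid, frozenset(genes))
    return GeneSetCollection(collection_name or Path(path).stem, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for pid in sorted(collection.sets):
        pname, genes = collection.sets[pid]
        lines.append("\t".join([pid, pname, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "overlap": r.overlap_count,
                "p_value": r.p_value,
                "adj_p": r.adj_p,
                "rank": r.rank,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
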
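"""Disease expression signatures from differential-expression tables.

A *gene table* is a :class:`pandas.DataFrame` with one row per gene and
columns ``gene_id``, ``log_fc``, ``p_value`` and (optionally, until adjusted)
``adj_p``. Tables are typically read from per-contrast TSV files produced by
an upstream differential-expression fit; normalisation and model fitting are
deliberately out of scope here.

A *disease signature* is the ordered set of most up- and most down-regulated
significant genes, cut under one of two configurations:

* ``split`` — the top ``n_up`` up-regulated and top ``n_down`` down-regulated
  genes (defaults 250/250), kept as two directed lists;
* ``combined`` — the top ``n_combined`` genes by absolute log fold change
  regardless of direction (default 500), kept as a single list with
  per-gene direction metadata.

Genes are ranked within direction by log-fold-change magnitude; ties are
broken lexicographically by ``gene_id`` so outputs are bit-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureConfig",
    "DiseaseSignature",
    "SignatureError",
    "adjust_pvalues_bh",
    "build_disease_signature",
    "read_gene_table",
    "write_signature_json",
    "read_signature_json",
    "write_signature_tsv",
]

GENE_TABLE_COLUMNS = ("gene_id", "log_fc", "p_value")


class SignatureError(ValueError):
    """Raised when a signature cannot be constructed from a gene table."""


@dataclass(frozen=True)
class SignatureConfig:
    """How a disease signature is cut from a gene table.

    Parameters
    ----------
    mode:
        ``"split"`` (directed top-N lists) or ``"combined"``
        (single direction-free list).
    n_up, n_down:
        Sizes of the up/down lists in split mode.
    n_combined:
        Size of the single list in combined mode.
    """

    mode: str = "split"
    n_up: int = 250
    n_down: int = 250
    n_combined: int = 500

    def __post_init__(self) -> None:
        if self.mode not in ("split", "combined"):
            raise ValueError(f"unknown signature mode {self.mode!r}")
        if self.mode == "split" and (self.n_up <= 0 or self.n_down <= 0):
            raise ValueError("split mode requires n_up > 0 and n_down > 0")
        if self.mode == "combined" and self.n_combined <= 0:
            raise ValueError("combined mode requires n_combined > 0")

    @property
    def label(self) -> str:
        if self.mode == "split":
            return f"split:{self.n_up},{self.n_down}"
        return f"combined:{self.n_combined}"


@dataclass
class DiseaseSignature:
    """Ordered up/down (or combined) gene lists for one disease contrast.

    In combined mode ``up_genes`` holds the full combined tag list,
    ``down_genes`` is empty and ``directions`` records each gene's sign.
    """

    contrast_id: str
    config: SignatureConfig
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        up, down = set(self.up_genes), set(self.down_genes)
        if len(up) != len(self.up_genes) or len(down) != len(self.down_genes):
            raise ValueError("signature gene lists contain duplicates")
        if up & down:
            raise ValueError("a gene appears in both up and down lists")

    @property
    def all_genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)


def adjust_pvalues_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment of raw p-values.

    Input order is preserved. Adjusted values equal
    ``min_{j >= i} p_(j) * m / j`` for the i-th smallest raw p, clipped to 1.

    Raises
    ------
    ValueError
        If any value lies outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def _validate_gene_table(table: pd.DataFrame) -> None:
    missing = [c for c in GENE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    if len(table) == 0:
        raise ValueError("gene table is empty")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"duplicate gene ids in table: {dupes}")
    p = table["p_value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_value column must lie in [0, 1]")


def build_disease_signature(
    table: pd.DataFrame,
    config: SignatureConfig,
    significance_cutoff: float = 0.05,
    contrast_id: str | None = None,
) -> DiseaseSignature:
    """Cut a disease signature from a gene table under one configuration.

    Genes with BH-adjusted p below ``significance_cutoff`` are eligible;
    within each direction they are ranked by log-fold-change magnitude
    (ties by ``gene_id``). Lists are truncated to the configured sizes, or
    to the number of available significant genes if fewer.

    Raises
    ------
    SignatureError
        If a required direction has no significant gene.
    """
    _validate_gene_table(table)
    cid = contrast_id or str(table.attrs.get("contrast_id", "contrast"))
    work = table.copy()
    if "adj_p" not in work.columns or work["adj_p"].isna().any():
        work["adj_p"] = adjust_pvalues_bh(work["p_value"].to_numpy())
    sig = work[(work["adj_p"] < significance_cutoff) & (work["log_fc"] != 0.0)]

    if config.mode == "split":
        up = sig[sig["log_fc"] > 0].sort_values(
            ["log_fc", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        down = sig[sig["log_fc"] < 0].sort_values(
            ["log_fc", "gene_id"], ascending=[True, True], kind="mergesort"
        )
        if len(up) == 0:
            raise SignatureError(
                f"contrast {cid!r}: no significant up-regulated gene"
            )
        if len(down) == 0:
            raise SignatureError(
                f"contrast {cid!r}: no significant down-regulated gene"
            )
        up_genes = up["gene_id"].head(config.n_up).tolist()
        down_genes = down["gene_id"].head(config.n_down).tolist()
        directions = {g: "up" for g in up_genes}
        directions.update({g: "down" for g in down_genes})
        return DiseaseSignature(cid, config, up_genes, down_genes, directions)

    ordered = sig.assign(_abs=sig["log_fc"].abs()).sort_values(
        ["_abs", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    if len(ordered) == 0:
        raise SignatureError(f"contrast {cid!r}: no significant gene")
    top = ordered.head(config.n_combined)
    genes = top["gene_id"].tolist()
    directions = {
        g: ("up" if f > 0 else "down")
        for g, f in zip(top["gene_id"], top["log_fc"])
    }
    return DiseaseSignature(cid, config, genes, [], directions)


# ---------------------------------------------------------------------------
# I/O


def read_gene_table(path: str | Path, contrast_id: str | None = None) -> pd.DataFrame:
    """Read a per-contrast gene table TSV (``gene_id  log_fc  p_value [adj_p]``)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    _validate_gene_table(table)
    table.attrs["contrast_id"] = contrast_id or Path(path).stem
    return table


def write_signature_json(signature: DiseaseSignature, path: str | Path) -> None:
    payload = {
        "contrast_id": signature.contrast_id,
        "config": {
            "mode": signature.config.mode,
            "n_up": signature.config.n_up,
            "n_down": signature.config.n_down,
            "n_combined": signature.config.n_combined,
        },
        "up_genes": list(signature.up_genes),
        "down_genes": list(signature.down_genes),
        "directions": dict(signature.directions),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_signature_json(path: str | Path) -> DiseaseSignature:
    payload = json.loads(Path(path).read_text())
    cfg = SignatureConfig(**payload["config"])
    return DiseaseSignature(
        payload["contrast_id"],
        cfg,
        payload["up_genes"],
        payload["down_genes"],
        payload.get("directions", {}),
    )


def write_signature_tsv(signature: DiseaseSignature, path: str | Path) -> None:
    """Two-column TSV: gene_id, direction in {up, down}."""
    rows: Iterable[tuple[str, str]]
    if signature.config.mode == "split":
        rows = [(g, "up") for g in signature.up_genes] + [
            (g, "down") for g in signature.down_genes
        ]
    else:
        rows = [(g, signature.directions.get(g, "up")) for g in signature.up_genes]
    pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(
        path, sep="\t", index=False
    )
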
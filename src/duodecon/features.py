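"""Marker-gene selection: one-vs-rest Wilcoxon rank-sum DEGs per cell type.

For every cell type, each gene is tested with a two-sided Wilcoxon rank-sum
(Mann-Whitney) comparing cells of that type against all other cells on
log2 CPM expression.  P-values are Benjamini-Hochberg adjusted within the
cell type's test family; genes pass with adjusted p below the cutoff and a
positive log fold change (difference of mean log2 expression, in-type minus
rest).  Survivors are ranked by log fold change, ties broken by gene
identifier, and the per-type lists are unioned (optionally across several
references) into the ordered gene list used for training and prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pseudobulk import normalize_log_cpm

__all__ = ["GeneList", "select_degs", "union_gene_lists", "intersect_with_bulk"]


@dataclass
class GeneList:
    """Ordered unique gene identifiers with per-gene provenance tags."""

    genes: list[str]
    provenance: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        prov = [";".join(f"{r}:{t}" for r, t in sorted(self.provenance.get(g, ())))
                for g in self.genes]
        return pd.DataFrame({"gene": self.genes, "provenance": prov})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneList":
        prov = {}
        for g, p in zip(df["gene"], df["provenance"]):
            if isinstance(p, str) and p:
                prov[g] = {tuple(item.split(":", 1)) for item in p.split(";")}
        return cls(list(df["gene"]), prov)


def _log_expression(ref) -> np.ndarray:
    X = ref.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return normalize_log_cpm(np.asarray(X, dtype=np.float64), axis=1)


def select_degs(ref, top_n: int | None = 285, p_cutoff: float = 0.1,
                ref_name: str | None = None) -> GeneList:
    """One-vs-rest rank-sum DEG selection on a single annotated reference.

    ``top_n=None`` keeps every passing gene.  Cell types with fewer than two
    cells are skipped with a warning.  Returns the union over cell types,
    ordered by cell type then descending log fold change, with provenance.
    """
    types = list(ref.obs["cell_type"].cat.categories)
    if len(types) < 2:
        raise ValueError("need at least two cell types for one-vs-rest selection")
    if ref_name is None:
        ref_name = str(ref.uns.get("name", "ref"))
    logx = _log_expression(ref)
    gene_ids = np.asarray(ref.var_names)
    labels = ref.obs["cell_type"].to_numpy()

    genes: list[str] = []
    provenance: dict[str, set] = {}
    for t in types:
        in_mask = labels == t
        n_in = int(in_mask.sum())
        if n_in < 2:
            warnings.warn(f"cell type {t!r} has {n_in} cells; skipped in DEG selection")
            continue
        a = logx[in_mask]
        b = logx[~in_mask]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        lfc = a.mean(axis=0) - b.mean(axis=0)
        keep = np.flatnonzero((padj < p_cutoff) & (lfc > 0))
        # descending logFC, ties broken lexicographically by gene identifier
        order = keep[np.lexsort((gene_ids[keep], -lfc[keep]))]
        if top_n is not None:
            order = order[:top_n]
        for gi in order:
            gid = gene_ids[gi]
            if gid not in provenance:
                genes.append(gid)
                provenance[gid] = set()
            provenance[gid].add((ref_name, str(t)))
    return GeneList(genes, provenance)


def union_gene_lists(lists: list[GeneList]) -> GeneList:
    """Union across references, preserving first-appearance order."""
    genes: list[str] = []
    provenance: dict[str, set] = {}
    for gl in lists:
        for g in gl.genes:
            if g not in provenance:
                genes.append(g)
                provenance[g] = set()
            provenance[g] |= gl.provenance.get(g, set())
    return GeneList(genes, provenance)


def intersect_with_bulk(gene_list: GeneList, bulk_genes) -> GeneList:
    """Restrict to genes present in the bulk matrix, preserving list order."""
    bulk = set(bulk_genes)
    kept = [g for g in gene_list.genes if g in bulk]
    if not kept:
        raise ValueError("no genes shared between the gene list and the bulk matrix")
    return GeneList(kept, {g: gene_list.provenance.get(g, set()) for g in kept})
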
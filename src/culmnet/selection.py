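"""Trait-specific candidate-gene filtration.

Implements the biomarker short-listing logic: genes of a module positively
and significantly correlated to a trait, the top-k gene-significance list
across all modules, and the restrictive intersection "in the trait's module
but not in the antagonistic trait's module".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .containers import ValidationError
from .network import ModuleAssignment

__all__ = [
    "CandidateGeneList",
    "positive_subset",
    "top_k_by_significance",
    "trait_specific_candidates",
    "module_overlap",
]


@dataclass
class CandidateGeneList:
    """Ordered candidate genes for one trait (GS-descending, id tie-break)."""

    trait: str
    target_module: str
    excluded_module: str
    table: pd.DataFrame  # columns: gene, module, r, GS, p, rank

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def _module_genes(assignment: ModuleAssignment, module: str) -> set:
    if module not in set(assignment.labels):
        raise ValidationError(f"unknown module {module!r}")
    return set(assignment.genes_in(module))


def positive_subset(
    assignment: ModuleAssignment,
    gs: pd.DataFrame,
    module: str,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list:
    """Genes of a module significantly positively correlated to the trait.

    ``adjust="bh"`` applies Benjamini-Hochberg to the module's p-values
    before thresholding; the default uses unadjusted p < alpha.  Returns the
    qualifying gene ids sorted lexicographically.
    """
    members = _module_genes(assignment, module)
    sub = gs.loc[[g for g in gs.index if g in members]]
    p = sub["p"].to_numpy()
    if adjust == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    keep = (sub["r"].to_numpy() > 0) & (p < alpha)
    return sorted(sub.index[keep])


def top_k_by_significance(gs: pd.DataFrame, k: int = 100, signed: bool = False) -> pd.DataFrame:
    """Top-k genes by gene significance, independently of module labels.

    Ranks by GS = |r| (or signed r with ``signed=True``) descending, breaking
    ties lexicographically on gene id.  Returns the ordered table with a
    1-based ``rank`` column.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(gs):
        raise ValidationError(f"k={k} exceeds the {len(gs)} scored genes")
    key = gs["r"] if signed else gs["GS"]
    order = (
        pd.DataFrame({"_key": key.to_numpy(), "_gene": gs.index.to_numpy()})
        .sort_values(["_key", "_gene"], ascending=[False, True])
        .index
    )
    top = gs.iloc[order].head(k).copy()
    top["rank"] = range(1, k + 1)
    return top


def trait_specific_candidates(
    top: pd.DataFrame,
    assignment: ModuleAssignment,
    target: str,
    exclude: str = "none",
    trait: str | None = None,
) -> CandidateGeneList:
    """Restrict an ordered top list to the target module, dropping any gene of
    the excluded module; the GS ordering is preserved."""
    if target == exclude:
        raise ValidationError("target and excluded module must differ")
    target_genes = _module_genes(assignment, target)
    excluded_genes = _module_genes(assignment, exclude) if exclude != "none" else set()
    rows = []
    for gene, row in top.iterrows():
        if gene in target_genes and gene not in excluded_genes:
            rows.append(
                {
                    "gene": gene,
                    "module": assignment.labels[gene],
                    "r": row["r"],
                    "GS": row["GS"],
                    "p": row["p"],
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "module", "r", "GS", "p"])
    table["rank"] = range(1, len(table) + 1)
    trait_name = trait or (top["trait"].iloc[0] if "trait" in top.columns and len(top) else "")
    return CandidateGeneList(
        trait=trait_name, target_module=target, excluded_module=exclude, table=table
    )


def module_overlap(set_a, set_b):
    """Exact intersection of two gene sets, ids in sorted order."""
    ids = sorted(set(set_a) & set(set_b))
    return len(ids), ids
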
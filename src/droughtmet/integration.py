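"""Pathway-level integration of metabolomic and transcriptomic hit lists.

Each omic layer is tested separately for over-representation of its hits in
a pathway's annotated feature set (one-sided hypergeometric / Fisher's exact
upper tail), and the two per-omic p-values are merged with Fisher's combined
probability test: X = -2 * sum(ln p_i) ~ chi-square with 2k degrees of
freedom under the null. An omic with no annotated members in a pathway
contributes p = 1 (no evidence), so gene-only pathways are still rankable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd
from scipy import stats


def overrepresentation_p(
    n_selected_in_set: int, n_selected: int, n_set: int, n_universe: int
) -> float:
    """Upper-tail hypergeometric probability of >= the observed overlap.

    ``n_selected`` hits drawn from a universe of ``n_universe`` features of
    which ``n_set`` belong to the pathway; returns P(overlap >= observed).
    """
    if min(n_selected_in_set, n_selected, n_set, n_universe) < 0:
        raise ValueError("counts must be non-negative")
    if n_selected_in_set > min(n_selected, n_set):
        raise ValueError(
            f"overlap {n_selected_in_set} exceeds min(selected={n_selected}, "
            f"set={n_set})"
        )
    if max(n_selected, n_set) > n_universe:
        raise ValueError("selected and set sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(n_selected_in_set - 1, n_universe, n_set, n_selected))


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's combined probability over independent p-values.

    chi2 survival of -2 * sum(ln p) at 2k degrees of freedom. Exact identity:
    combining a single p-value returns it unchanged.
    """
    ps = list(pvalues)
    if not ps:
        raise ValueError("need at least one p-value")
    for p in ps:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    x = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x, 2 * len(ps)))


@dataclass
class PathwayIntegration:
    """One pathway's joint gene/metabolite enrichment record."""

    pathway: str
    unique_genes: int
    unique_metabolites: int
    p_genes: float
    p_metabolites: float
    p_combined: float


def integrate_pathways(
    gene_hits: Iterable[str],
    gene_universe: Iterable[str],
    met_hits: Iterable[str],
    met_universe: Iterable[str],
    pathway_annotation: Dict[str, Tuple[Iterable[str], Iterable[str]]],
) -> pd.DataFrame:
    """Joint pathway enrichment of differential genes and metabolites.

    ``pathway_annotation`` maps a pathway to its (gene set, metabolite set).
    Duplicated identifiers are counted once. Pathways with neither genes nor
    metabolites annotated are skipped (listed in ``df.attrs['skipped']``).
    Rows are sorted by combined p-value.
    """
    gene_hits, gene_universe = set(gene_hits), set(gene_universe)
    met_hits, met_universe = set(met_hits), set(met_universe)
    if not gene_hits <= gene_universe:
        raise ValueError("gene hits must be a subset of the gene universe")
    if not met_hits <= met_universe:
        raise ValueError("metabolite hits must be a subset of the metabolite universe")
    if not pathway_annotation:
        raise ValueError("empty pathway annotation")

    rows: List[PathwayIntegration] = []
    skipped: List[str] = []
    for pathway, (genes, mets) in pathway_annotation.items():
        genes = set(genes) & gene_universe
        mets = set(mets) & met_universe
        if not genes and not mets:
            skipped.append(pathway)
            continue
        if genes:
            p_g = overrepresentation_p(
                len(gene_hits & genes), len(gene_hits), len(genes), len(gene_universe)
            )
        else:
            p_g = 1.0
        if mets:
            p_m = overrepresentation_p(
                len(met_hits & mets), len(met_hits), len(mets), len(met_universe)
            )
        else:
            p_m = 1.0
        rows.append(
            PathwayIntegration(
                pathway, len(gene_hits & genes), len(met_hits & mets),
                p_g, p_m, fisher_combine([p_g, p_m]),
            )
        )

    df = pd.DataFrame(
        [
            {
                "pathway": r.pathway, "unique_genes": r.unique_genes,
                "unique_metabolites": r.unique_metabolites, "p_genes": r.p_genes,
                "p_metabolites": r.p_metabolites, "p_combined": r.p_combined,
            }
            for r in rows
        ]
    )
    if len(df) == 0:
        df = pd.DataFrame(columns=[
            "pathway", "unique_genes", "unique_metabolites",
            "p_genes", "p_metabolites", "p_combined",
        ])
    df = df.sort_values(["p_combined", "pathway"]).set_index("pathway")
    df.attrs["skipped"] = skipped
    return df


def read_annotation(path: str) -> Dict[str, Tuple[Set[str], Set[str]]]:
    """Read a pathway annotation table.

    Expected columns: ``pathway_id``, ``feature_id``, ``feature_type`` with
    feature_type in {gene, metabolite}; TSV or CSV by extension.
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("pathway_id", "feature_id", "feature_type"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing column {col!r}")
    bad = set(df["feature_type"]) - {"gene", "metabolite"}
    if bad:
        raise ValueError(f"unknown feature_type values: {sorted(bad)}")
    out: Dict[str, Tuple[Set[str], Set[str]]] = {}
    for pw, grp in df.groupby("pathway_id"):
        genes = set(grp.loc[grp["feature_type"] == "gene", "feature_id"])
        mets = set(grp.loc[grp["feature_type"] == "metabolite", "feature_id"])
        out[str(pw)] = (genes, mets)
    return out
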
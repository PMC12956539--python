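"""Cell-type specificity of MR effects and weighted drug-target priority.

Specificity: a gene's absolute causal effects |beta| across the n immune
cell types are normalized to proportions p_i and summarized by normalized
Shannon entropy H = -sum p_i log2 p_i / log2 n, so H = 0 means the entire
effect sits in one lineage and H = 1 means a perfectly uniform effect.
Genes with H < 0.5 are called lineage-specific, H > 0.8 diffuse, the rest
intermediate.

Prioritization: four binary evidence criteria — (i) prior disease-locus
evidence, (ii) membership in a disease-relevant pathway, (iii) an
approved/investigational drug targeting the protein, (iv) a druggable
structure class — weighted +2, +1, +1, +0.5. Composite score >= 4 is
high priority, 3-3.5 medium, <= 2.5 low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EntropyProfile",
    "GenePriority",
    "PRIORITY_WEIGHTS",
    "entropy",
    "rank_specific_genes",
    "priority_score",
    "priority_tier",
    "annotate_druggability",
    "prioritize_genes",
]

PRIORITY_WEIGHTS = (2.0, 1.0, 1.0, 0.5)

LINEAGE_SPECIFIC_MAX = 0.5
DIFFUSE_MIN = 0.8


@dataclass(frozen=True)
class EntropyProfile:
    """Normalized-entropy summary of one gene's per-lineage |MR effects|.

    ``abs_beta`` keeps the input vector (NaN = gene untested in that
    lineage); ``p`` holds proportions over the non-missing entries.
    """

    gene: str
    abs_beta: np.ndarray
    p: np.ndarray
    H: float
    top_cell_type: str
    class_: str  # lineage_specific | intermediate | diffuse
    cell_types: tuple[str, ...]

    @property
    def mean_abs_beta(self) -> float:
        return float(np.nanmean(self.abs_beta))


def entropy(abs_beta: Sequence[float], gene: str = "",
            cell_types: Optional[Sequence[str]] = None,
            highlight_threshold: float = 0.2) -> EntropyProfile:
    """Normalized Shannon entropy of |MR effect| proportions.

    Missing lineages (NaN) are excluded from both the normalization sum
    and the lineage count n — a gene untested in a cell type is not a gene
    with zero effect there. Zero entries use the 0*log(0) = 0 convention.

    Raises for n < 2 non-missing lineages (log2(1) = 0 denominator) and
    for an all-zero vector (proportions undefined).
    """
    x = np.abs(np.asarray(abs_beta, dtype=float))
    if cell_types is None:
        cell_types = tuple(f"CT{i + 1}" for i in range(x.size))
    cell_types = tuple(cell_types)
    if len(cell_types) != x.size:
        raise ValueError("cell_types length does not match abs_beta")
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("entropy needs >= 2 non-missing lineages")
    vals = x[mask]
    total = vals.sum()
    if total <= 0:
        raise ValueError("entropy undefined: all effects are zero")
    p_obs = vals / total
    nz = p_obs[p_obs > 0]
    H = float(-np.sum(nz * np.log2(nz)) / np.log2(n))
    # snap floating-point round-off at the analytic boundaries
    if H < 1e-12:
        H = 0.0
    elif H > 1.0 - 1e-12:
        H = 1.0

    p_full = np.full_like(x, np.nan)
    p_full[mask] = p_obs
    top_i = int(np.nanargmax(p_full))
    if H < LINEAGE_SPECIFIC_MAX:
        cls = "lineage_specific"
    elif H > DIFFUSE_MIN:
        cls = "diffuse"
    else:
        cls = "intermediate"
    return EntropyProfile(gene=gene, abs_beta=x, p=p_full, H=H,
                          top_cell_type=cell_types[top_i], class_=cls,
                          cell_types=cell_types)


def rank_specific_genes(profiles: Sequence[EntropyProfile], k: int,
                        highlight_threshold: float = 0.2) -> pd.DataFrame:
    """Most lineage-restricted genes: ascending by H, ties broken by
    descending mean |beta| then gene symbol. Returns the first ``k`` with
    their dominant cell type; asking for more than available returns all,
    flagged in the ``truncated`` attribute column.

    ``highlight_threshold`` marks an extra reporting band (H below it) for
    strikingly lineage-restricted genes; it plays no role in the ordering.
    """
    if not profiles:
        raise ValueError("no profiles to rank")
    ordered = sorted(profiles, key=lambda pr: (pr.H, -pr.mean_abs_beta, pr.gene))
    take = ordered[:k]
    df = pd.DataFrame({
        "gene": [pr.gene for pr in take],
        "H": [pr.H for pr in take],
        "mean_abs_beta": [pr.mean_abs_beta for pr in take],
        "top_cell_type": [pr.top_cell_type for pr in take],
        "class": [pr.class_ for pr in take],
        "highlight": [pr.H < highlight_threshold for pr in take],
    })
    df.attrs["truncated"] = k > len(profiles)
    return df


@dataclass(frozen=True)
class GenePriority:
    gene: str
    disease_locus: bool
    pathway_member: bool
    has_drug: bool
    druggable: bool
    score: float
    tier: str  # high | medium | low


def priority_tier(score: float) -> str:
    """Printed tier bands: >= 4 high, 3-3.5 medium, <= 2.5 low. The
    reachable score grid {0, 0.5, ..., 4.5} leaves no gaps between bands."""
    if score >= 4:
        return "high"
    if score >= 3:
        return "medium"
    return "low"


def priority_score(disease_locus: bool, pathway_member: bool, has_drug: bool,
                   druggable: bool, gene: str = "",
                   weights: tuple[float, float, float, float] = PRIORITY_WEIGHTS
                   ) -> GenePriority:
    """Composite evidence score: weighted sum of the four criteria."""
    flags = (disease_locus, pathway_member, has_drug, druggable)
    score = float(sum(w for w, f in zip(weights, flags) if f))
    return GenePriority(gene=gene, disease_locus=disease_locus,
                        pathway_member=pathway_member, has_drug=has_drug,
                        druggable=druggable, score=score,
                        tier=priority_tier(score))


DRUG_TABLE_COLUMNS = ("gene", "drug_id", "interaction_type", "source",
                      "druggable_class")


def annotate_druggability(genes: Sequence[str],
                          drug_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene drug-evidence flags from a static annotation snapshot.

    ``has_drug`` — the gene has at least one documented drug interaction;
    ``druggable`` — at least one row carries a non-empty druggable class.
    Genes absent from the table get both flags False and the annotation
    "undrugged".
    """
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in drug_table.columns]
    if missing:
        raise ValueError(f"drug table missing column(s): {', '.join(missing)}")
    tab = drug_table.copy()
    tab["druggable_class"] = tab["druggable_class"].fillna("").astype(str)
    by_gene = tab.groupby("gene")
    has_drug = by_gene.size()
    druggable = by_gene["druggable_class"].apply(lambda s: (s.str.len() > 0).any())
    rows = []
    for g in genes:
        hd = g in has_drug.index and has_drug[g] > 0
        dg = bool(druggable.get(g, False))
        rows.append({
            "gene": g, "has_drug": bool(hd), "druggable": dg,
            "annotation": "drugged" if hd else "undrugged",
        })
    return pd.DataFrame(rows)


def prioritize_genes(genes: Sequence[str], disease_table: pd.DataFrame,
                     pathway_table: pd.DataFrame,
                     drug_table: pd.DataFrame) -> pd.DataFrame:
    """Score every gene against the four evidence criteria.

    ``disease_table`` and ``pathway_table`` need a ``gene`` column listing
    genes with that line of evidence; drug evidence comes from
    :func:`annotate_druggability`.
    """
    disease = set(disease_table["gene"])
    pathway = set(pathway_table["gene"])
    drug_flags = annotate_druggability(genes, drug_table).set_index("gene")
    rows = []
    for g in genes:
        pr = priority_score(g in disease, g in pathway,
                            bool(drug_flags.loc[g, "has_drug"]),
                            bool(drug_flags.loc[g, "druggable"]), gene=g)
        rows.append({
            "gene": g, "disease_locus": pr.disease_locus,
            "pathway_member": pr.pathway_member, "has_drug": pr.has_drug,
            "druggable": pr.druggable, "score": pr.score, "tier": pr.tier,
            "annotation": drug_flags.loc[g, "annotation"],
        })
    return pd.DataFrame(rows)
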
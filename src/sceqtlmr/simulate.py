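"""Synthetic summary-statistics generator with known causal ground truth.

Emulates the study design the pipeline targets: cis-eQTL summary
statistics for genes across 14 immune cell types (a 982-donor eQTL cohort)
and an outcome GWAS with a configurable true causal effect theta of
expression on the trait. Statistics are generated directly at the summary
level on the standardized scale (unit-variance genotypes and traits):

- within a cis locus of m variants, LD is AR(1) with correlation
  rho^|i-j|;
- true marginal eQTL effects are R @ b where b holds the causal variant
  effects; the estimate adds MVN(0, se_exp^2 R) sampling noise with
  se_exp = 1/sqrt(n_eqtl);
- outcome marginal effects are theta * (R @ b) plus optional direct
  (pleiotropic) variant effects, with MVN(0, se_out^2 R) noise at
  se_out = 1/sqrt(n_gwas).

Every generator is deterministic under the config seed; per-locus streams
are derived from (seed, gene, cell type) so a locus can be regenerated in
isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, toeplitz

from .coloc import ColocInput
from .sumstats import ExposureDataset, VariantAssociation

__all__ = [
    "ONEK1K_CELL_TYPES",
    "SimConfig",
    "simulate_ld",
    "simulate_locus",
    "simulate_study",
    "simulate_coloc_pair",
    "simulate_annotations",
]

# OneK1K-style peripheral immune cell subsets (14 lineages).
ONEK1K_CELL_TYPES = (
    "CD4 NC", "CD4 ET", "CD4 SOX4", "CD8 NC", "CD8 ET", "CD8 S100B",
    "NK", "NK R", "B Mem", "B IN", "Plasma", "Mono C", "Mono NC", "DC",
)

# Non-palindromic allele pairs (strand-unambiguous), sampled for variants.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated study: 14 immune cell types, a 982-donor
    eQTL cohort, and a desk-scale outcome GWAS of 50,000 (the real outcome
    cohort of 484,598 is reachable by setting ``n_gwas``). ``theta`` is
    the true causal effect of expression on the outcome — a scalar applied
    everywhere or an (n_genes, n_cell_types) matrix. ``eqtl_beta_scale``
    is the SD of causal cis-effects on the standardized scale; 0.3 puts
    single-variant F-statistics near 90, the strong-instrument regime of
    retained cis-eQTLs. ``seed`` is mandatory.
    """

    seed: int
    n_genes: int = 20
    n_cell_types: int = 14
    m_variants: int = 50
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_eqtl: int = 982
    n_gwas: int = 50_000
    theta: Union[float, np.ndarray] = 0.0
    n_causal_eqtl: int = 3
    pleiotropy_frac: float = 0.0
    eqtl_beta_scale: float = 0.3
    pleiotropy_beta_scale: float = 0.05
    # annotation-table marginal frequencies (drug frequency 0.41 mirrors
    # the 62/118 drugged fraction of the emulated study)
    drug_freq: float = 0.41
    druggable_freq: float = 0.30
    disease_freq: float = 0.25
    pathway_freq: float = 0.40
    ppi_edge_prob: float = 0.08
    n_hubs: int = 1
    hub_attach_frac: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "n_cell_types", "m_variants", "n_eqtl",
                     "n_gwas", "n_causal_eqtl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_causal_eqtl > self.m_variants:
            raise ValueError("n_causal_eqtl cannot exceed m_variants")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must lie in [0,1]")
        th = np.asarray(self.theta, dtype=float)
        if not np.all(np.isfinite(th)):
            raise ValueError("theta must be finite")

    def cell_types(self) -> tuple[str, ...]:
        if self.n_cell_types <= len(ONEK1K_CELL_TYPES):
            return ONEK1K_CELL_TYPES[: self.n_cell_types]
        extra = tuple(f"CT{i + 1}" for i in
                      range(len(ONEK1K_CELL_TYPES), self.n_cell_types))
        return ONEK1K_CELL_TYPES + extra

    def genes(self) -> tuple[str, ...]:
        return tuple(f"GENE{i + 1:03d}" for i in range(self.n_genes))

    def theta_for(self, gene_idx: int, ct_idx: int) -> float:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim == 0:
            return float(th)
        return float(th[gene_idx, ct_idx])


def _locus_rng(config: SimConfig, gene: str, cell_type: str) -> np.random.Generator:
    tag = zlib.crc32(f"{gene}|{cell_type}".encode())
    return np.random.default_rng([config.seed, tag])


def simulate_ld(m: int, rho: float) -> np.ndarray:
    """AR(1) LD correlation matrix R[i,j] = rho^|i-j| (positive-definite
    by construction for 0 <= rho < 1)."""
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0,1)")
    if m < 1:
        raise ValueError("m must be positive")
    return toeplitz(rho ** np.arange(m))


def _zp(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_locus(config: SimConfig, gene: str, cell_type: str,
                   gene_idx: int = 0, ct_idx: int = 0,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[ExposureDataset, pd.DataFrame, dict]:
    """One gene x cell-type cis locus plus its outcome associations.

    Returns the exposure dataset, the outcome summary-statistic table for
    the same variants, and a truth record (theta, causal variant ids,
    pleiotropic variant ids, noiseless marginal effects, LD matrix).
    Variant ids are unique to the locus, so loci from different genes or
    cell types never collide in a merged outcome table.
    """
    if rng is None:
        rng = _locus_rng(config, gene, cell_type)
    m = config.m_variants
    theta = config.theta_for(gene_idx, ct_idx)
    R = simulate_ld(m, config.ld_rho)
    L = cholesky(R, lower=True) if config.ld_rho > 0 else None

    mafs = rng.uniform(*config.maf_range, size=m)
    causal = np.sort(rng.choice(m, size=config.n_causal_eqtl, replace=False))
    b = np.zeros(m)
    b[causal] = rng.normal(0.0, config.eqtl_beta_scale, size=config.n_causal_eqtl)

    n_pleio = int(round(config.pleiotropy_frac * config.n_causal_eqtl))
    pleio = np.sort(rng.choice(causal, size=n_pleio, replace=False)) if n_pleio else np.array([], dtype=int)
    alpha = np.zeros(m)
    if n_pleio:
        alpha[pleio] = rng.normal(0.0, config.pleiotropy_beta_scale, size=n_pleio)

    def _noise(se: float) -> np.ndarray:
        eps = rng.standard_normal(m)
        return se * (L @ eps if L is not None else eps)

    beta_exp_true = R @ b
    se_exp = 1.0 / np.sqrt(config.n_eqtl)
    beta_exp = beta_exp_true + _noise(se_exp)

    beta_out_true = theta * beta_exp_true + R @ alpha
    se_out = 1.0 / np.sqrt(config.n_gwas)
    beta_out = beta_out_true + _noise(se_out)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    base_pos = 1 + 100_000 * (gene_idx * config.n_cell_types + ct_idx)
    ids = [f"{gene}:{cell_type}:v{i:03d}".replace(" ", "_") for i in range(m)]
    p_exp = _zp(beta_exp, np.full(m, se_exp))
    p_out = _zp(beta_out, np.full(m, se_out))

    assocs = tuple(
        VariantAssociation(
            variant_id=ids[i], chrom="1", pos=base_pos + i,
            effect_allele=_ALLELE_PAIRS[pair_idx[i]][0],
            other_allele=_ALLELE_PAIRS[pair_idx[i]][1],
            eaf=float(mafs[i]), beta=float(beta_exp[i]), se=float(se_exp),
            pvalue=float(p_exp[i]), n=config.n_eqtl)
        for i in range(m)
    )
    exposure = ExposureDataset(gene=gene, cell_type=cell_type, associations=assocs)
    outcome = pd.DataFrame({
        "variant_id": ids, "chrom": "1", "pos": np.arange(base_pos, base_pos + m),
        "effect_allele": [_ALLELE_PAIRS[j][0] for j in pair_idx],
        "other_allele": [_ALLELE_PAIRS[j][1] for j in pair_idx],
        "eaf": mafs, "beta": beta_out, "se": se_out, "pvalue": p_out,
        "n": config.n_gwas,
    })
    truth = {
        "gene": gene, "cell_type": cell_type, "theta": theta,
        "causal_ids": [ids[i] for i in causal],
        "pleiotropic_ids": [ids[i] for i in pleio],
        "beta_exp_true": beta_exp_true, "beta_out_true": beta_out_true,
        "ld": R,
    }
    return exposure, outcome, truth


def simulate_study(config: SimConfig
                   ) -> tuple[list[ExposureDataset], pd.DataFrame, dict, list[dict]]:
    """Full input bundle: exposure datasets for every gene x cell type,
    one merged outcome table, a per-locus LD map keyed by
    (gene, cell_type), and the truth records."""
    exposures, outcomes, ld_map, truths = [], [], {}, []
    for gi, gene in enumerate(config.genes()):
        for ci, ct in enumerate(config.cell_types()):
            exp, out, truth = simulate_locus(config, gene, ct, gi, ci)
            exposures.append(exp)
            outcomes.append(out)
            ld_map[(gene, ct)] = truth["ld"]
            truths.append(truth)
    outcome = pd.concat(outcomes, ignore_index=True)
    return exposures, outcome, ld_map, truths


def simulate_coloc_pair(shared: bool, config: SimConfig,
                        z_causal: float = 8.0,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[ColocInput, dict]:
    """A locus for colocalization with a known hypothesis label.

    ``shared=True``: one causal variant drives both traits (truth H4);
    ``shared=False``: two LD-separated causal variants, one per trait
    (truth H3). Causal z-scores are centered on ``z_causal``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xC01C])
    m = config.m_variants
    R = simulate_ld(m, config.ld_rho)
    L = cholesky(R, lower=True) if config.ld_rho > 0 else None

    se1 = 1.0 / np.sqrt(config.n_eqtl)
    se2 = 1.0 / np.sqrt(config.n_gwas)
    c1 = m // 4
    c2 = c1 if shared else (3 * m) // 4

    def _trait(c: int, se: float) -> np.ndarray:
        b = np.zeros(m)
        b[c] = z_causal * se
        mean = R @ b
        eps = rng.standard_normal(m)
        return mean + se * (L @ eps if L is not None else eps)

    beta1 = _trait(c1, se1)
    beta2 = _trait(c2, se2)
    ids = tuple(f"cv{i:03d}" for i in range(m))
    inp = ColocInput(
        gene="SIMGENE", cell_type=ONEK1K_CELL_TYPES[0], variant_ids=ids,
        beta1=beta1, varbeta1=np.full(m, se1**2),
        beta2=beta2, varbeta2=np.full(m, se2**2),
    )
    truth = {"label": "H4" if shared else "H3",
             "causal1": ids[c1], "causal2": ids[c2],
             "r2_causal": float(R[c1, c2] ** 2)}
    return inp, truth


def simulate_annotations(genes: Sequence[str], config: SimConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> dict[str, pd.DataFrame]:
    """Seeded annotation tables: drug interactions, disease evidence,
    pathway membership, and a weighted PPI edge list with planted hubs.

    Hubs attach to ``hub_attach_frac`` of all genes with high-confidence
    scores, so their degree (and betweenness) dwarfs the sparse background
    graph — the planted structure a hub-ranking step should recover.
    Returns {"drug", "disease", "pathway", "ppi", "hubs"}.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xA110])
    genes = list(genes)
    n = len(genes)

    interaction_types = ("inhibitor", "agonist", "antagonist", "modulator")
    drug_rows = []
    for g in genes:
        if rng.random() >= config.drug_freq:
            continue
        druggable = rng.random() < (config.druggable_freq / max(config.drug_freq, 1e-9))
        for _ in range(int(rng.integers(1, 4))):
            drug_rows.append({
                "gene": g, "drug_id": f"DB{int(rng.integers(0, 99999)):05d}",
                "interaction_type": str(rng.choice(interaction_types)),
                "source": "synthetic",
                "druggable_class": "small molecule" if druggable else "",
            })
    drug = pd.DataFrame(drug_rows, columns=["gene", "drug_id",
                                            "interaction_type", "source",
                                            "druggable_class"])

    disease = pd.DataFrame({"gene": [g for g in genes
                                     if rng.random() < config.disease_freq]})
    pathway = pd.DataFrame({"gene": [g for g in genes
                                     if rng.random() < config.pathway_freq]})

    hubs = [str(g) for g in rng.choice(genes, size=min(config.n_hubs, n),
                                       replace=False)]
    edge_rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.ppi_edge_prob:
                edge_rows.append({"gene_a": genes[i], "gene_b": genes[j],
                                  "score": float(rng.uniform(0.4, 1.0))})
    for hub in hubs:
        others = [g for g in genes if g != hub]
        n_attach = max(1, int(round(config.hub_attach_frac * len(others))))
        for g in rng.choice(others, size=n_attach, replace=False):
            edge_rows.append({"gene_a": hub, "gene_b": str(g),
                              "score": float(rng.uniform(0.75, 1.0))})
    ppi = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "score"])
    return {"drug": drug, "disease": disease, "pathway": pathway,
            "ppi": ppi, "hubs": pd.DataFrame({"gene": hubs})}
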
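"""Bayesian colocalization of an eQTL signal and a GWAS signal at one locus.

Under the single-causal-variant assumption the evidence at a locus is
summarized by five hypotheses: H0 no association with either trait, H1/H2
association with one trait only, H3 two distinct causal variants, H4 one
shared causal variant. Per-variant approximate Bayes factors (Wakefield)
are combined with prior probabilities p1, p2, p12 into posterior
probabilities PPH0..PPH4; a high PPH4 supports a shared causal variant,
the evidence convention used downstream being PPH4 >= 0.8.

All hypothesis sums are done in log space (log-sum-exp) so loci with
hundreds of strong variants cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .sumstats import HarmonizedSet

__all__ = [
    "ColocInput",
    "ColocResult",
    "DEFAULT_PRIORS",
    "prior_effect_variance",
    "wakefield_labf",
    "coloc_abf",
    "coloc_input_from_harmonized",
]

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12


def prior_effect_variance(trait_type: str, sdY: float = 1.0) -> float:
    """Prior variance W of the true effect at a causal variant.

    Quantitative traits: (0.15 * sdY)^2 per SD of the trait; case-control
    traits: 0.2^2 on the log-odds scale.
    """
    if trait_type == "quant":
        if sdY <= 0:
            raise ValueError("sdY must be positive")
        return (0.15 * sdY) ** 2
    if trait_type == "cc":
        return 0.2**2
    raise ValueError("trait_type must be 'quant' or 'cc'")


def wakefield_labf(beta, varbeta, prior_w: float):
    """Log approximate Bayes factor for one variant (vectorized).

    With shrinkage r = W/(W + V) and z = beta/sqrt(V):
    lABF = 0.5 * (log(1 - r) + r * z^2). Positive when the data favor an
    effect over the null; -> 0 as V -> infinity (no information).
    """
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if np.any(varbeta <= 0):
        raise ValueError("varbeta must be positive")
    if prior_w <= 0:
        raise ValueError("prior_w must be positive")
    r = prior_w / (prior_w + varbeta)
    z2 = beta**2 / varbeta
    out = 0.5 * (np.log1p(-r) + r * z2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ColocInput:
    """Aligned per-variant effects for two traits at one gene locus.

    Trait 1 is expression (the eQTL), trait 2 the outcome GWAS. ``varbeta``
    is the squared standard error. Priors: p1/p2 = probability a variant is
    causal for trait 1/2 only, p12 = causal for both; p1+p2+p12 < 1.
    """

    gene: str
    cell_type: str
    variant_ids: tuple[str, ...]
    beta1: np.ndarray
    varbeta1: np.ndarray
    beta2: np.ndarray
    varbeta2: np.ndarray
    type1: str = "quant"
    type2: str = "quant"
    sdY1: float = 1.0
    sdY2: float = 1.0
    p1: float = DEFAULT_PRIORS[0]
    p2: float = DEFAULT_PRIORS[1]
    p12: float = DEFAULT_PRIORS[2]

    def __post_init__(self):
        k = len(self.variant_ids)
        if k < 1:
            raise ValueError("need >= 1 shared variant")
        for name in ("beta1", "varbeta1", "beta2", "varbeta2"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (k,):
                raise ValueError(f"{name} has shape {v.shape}, expected ({k},)")
        if np.any(self.varbeta1 <= 0) or np.any(self.varbeta2 <= 0):
            raise ValueError("varbeta must be positive elementwise")
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")

    @property
    def k(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    gene: str
    cell_type: str
    pph: np.ndarray  # PPH0..PPH4, sums to 1
    n_variants: int
    h4_weights: np.ndarray  # per-variant posterior of being the shared causal
    priors: tuple[float, float, float]
    single_variant: bool = False  # PPH3 undefined (empty pair sum), set to 0

    @property
    def pph4(self) -> float:
        return float(self.pph[4])

    def colocalized(self, threshold: float = 0.8) -> bool:
        return self.pph4 >= threshold

    def as_dict(self) -> dict:
        return {
            "gene": self.gene, "cell_type": self.cell_type,
            "n_variants": self.n_variants,
            **{f"PPH{i}": float(self.pph[i]) for i in range(5)},
        }


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference underflows."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(inp: ColocInput) -> ColocResult:
    """Enumerate the five hypotheses from per-variant Wakefield lABFs.

    With S1 = sum_i exp(lABF1_i), S2 likewise and S12 = sum_i
    exp(lABF1_i + lABF2_i), the unnormalized hypothesis weights are
    H0 = 1, H1 = p1*S1, H2 = p2*S2, H3 = p1*p2*(S1*S2 - S12),
    H4 = p12*S12 — all evaluated in log space. A single-variant locus has
    an empty pair sum, so PPH3 is reported as 0 with ``single_variant``
    set.
    """
    l1 = wakefield_labf(inp.beta1, inp.varbeta1,
                        prior_effect_variance(inp.type1, inp.sdY1))
    l2 = wakefield_labf(inp.beta2, inp.varbeta2,
                        prior_effect_variance(inp.type2, inp.sdY2))
    lsum1 = float(logsumexp(l1))
    lsum2 = float(logsumexp(l2))
    lsum12 = float(logsumexp(l1 + l2))

    lH0 = 0.0
    lH1 = math.log(inp.p1) + lsum1
    lH2 = math.log(inp.p2) + lsum2
    lH4 = math.log(inp.p12) + lsum12
    single = inp.k == 1
    if single:
        lH3 = -math.inf
    else:
        lH3 = math.log(inp.p1) + math.log(inp.p2) + _logdiff(lsum1 + lsum2, lsum12)

    lh = np.array([lH0, lH1, lH2, lH3, lH4])
    pph = np.exp(lh - logsumexp(lh))
    pph = pph / pph.sum()

    l12 = l1 + l2
    h4w = np.exp(l12 - logsumexp(l12))
    return ColocResult(gene=inp.gene, cell_type=inp.cell_type, pph=pph,
                       n_variants=inp.k, h4_weights=h4w,
                       priors=(inp.p1, inp.p2, inp.p12), single_variant=single)


def coloc_input_from_harmonized(h: HarmonizedSet,
                                p1: float = DEFAULT_PRIORS[0],
                                p2: float = DEFAULT_PRIORS[1],
                                p12: float = DEFAULT_PRIORS[2],
                                type1: str = "quant",
                                type2: str = "quant") -> ColocInput:
    """Build a ColocInput from a harmonized exposure/outcome set (all
    variants retained at the locus, not just clumped instruments)."""
    return ColocInput(
        gene=h.gene, cell_type=h.cell_type, variant_ids=h.variant_ids,
        beta1=h.beta_exp, varbeta1=h.se_exp**2,
        beta2=h.beta_out, varbeta2=h.se_out**2,
        type1=type1, type2=type2, p1=p1, p2=p2, p12=p12,
    )
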
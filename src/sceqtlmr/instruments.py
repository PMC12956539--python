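"""Genetic-instrument selection for cis-eQTL exposures.

A variant qualifies as an instrument for a gene's expression in a cell
type if it (i) reaches the cis-eQTL significance threshold, (ii) survives
greedy LD clumping so retained instruments are near-independent, and
(iii) is a strong instrument by the F-statistic criterion (F >= 10 by
convention; weaker instruments bias two-sample MR toward the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sumstats import ExposureDataset, VariantAssociation

__all__ = [
    "InstrumentConfig",
    "SelectionResult",
    "f_statistic",
    "f_statistic_from_r2",
    "ld_clump",
    "select_instruments",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Thresholds for instrument selection.

    p_threshold : cis-eQTL significance cutoff (default 5e-5).
    clump_r2    : maximum squared correlation between retained instruments
                  (default 0.001).
    f_min       : minimum F-statistic; variants with F below this are
                  excluded, i.e. keep iff F >= f_min (default 10).
    """

    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    f_min: float = 10.0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0,1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must lie in [0,1]")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument strength, F = (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def f_statistic_from_r2(r2: float, n: int) -> float:
    """Alternative F from variance explained: (n-2) * r2 / (1 - r2)."""
    if not (0 <= r2 < 1):
        raise ValueError("r2 must lie in [0,1)")
    if n < 3:
        raise ValueError("n must be >= 3")
    return (n - 2) * r2 / (1 - r2)


def ld_clump(associations: Sequence[VariantAssociation], ld: np.ndarray,
             clump_r2: float) -> list[str]:
    """Greedy LD clumping; returns retained variant ids.

    Variants are visited in ascending p-value order (ties broken by
    lexicographic variant id); a variant is accepted iff its squared
    correlation with every already-accepted variant is <= ``clump_r2``.
    The result is therefore independent of input ordering.
    """
    k = len(associations)
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (k, k):
        raise ValueError(f"ld shape {ld.shape} does not match {k} associations")
    order = sorted(range(k), key=lambda i: (associations[i].pvalue,
                                            associations[i].variant_id))
    accepted: list[int] = []
    for i in order:
        if all(ld[i, j] ** 2 <= clump_r2 for j in accepted):
            accepted.append(i)
    return [associations[i].variant_id for i in accepted]


@dataclass(frozen=True)
class SelectionResult:
    """Filtered instruments plus a per-stage audit trail."""

    dataset: Optional[ExposureDataset]  # None when nothing survives
    retained_ids: tuple[str, ...]
    retained_indices: tuple[int, ...]  # positions in the input dataset
    audit: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return self.dataset is None


def select_instruments(dataset: ExposureDataset, ld: Optional[np.ndarray],
                       config: InstrumentConfig = InstrumentConfig()) -> SelectionResult:
    """Apply the three-stage instrument filter: p-value, LD clump, F-statistic.

    ``ld`` must be ordered like ``dataset.associations``; pass None to skip
    clumping (instruments assumed pre-pruned). An empty result is a valid
    outcome, flagged in the audit, never an exception.
    """
    assocs = dataset.associations
    n0 = len(assocs)

    sig_idx = [i for i, a in enumerate(assocs) if a.pvalue < config.p_threshold]
    removed_p = n0 - len(sig_idx)

    if ld is not None and len(sig_idx) > 1:
        sub_ld = np.asarray(ld, dtype=float)[np.ix_(sig_idx, sig_idx)]
        kept_ids = set(ld_clump([assocs[i] for i in sig_idx], sub_ld, config.clump_r2))
        clump_idx = [i for i in sig_idx if assocs[i].variant_id in kept_ids]
    else:
        clump_idx = sig_idx
    removed_ld = len(sig_idx) - len(clump_idx)

    final_idx = [i for i in clump_idx
                 if f_statistic(assocs[i].beta, assocs[i].se) >= config.f_min]
    removed_f = len(clump_idx) - len(final_idx)

    audit = {
        "gene": dataset.gene, "cell_type": dataset.cell_type,
        "n_input": n0, "removed_pvalue": removed_p, "removed_ld": removed_ld,
        "removed_weak": removed_f, "n_retained": len(final_idx),
        "empty": len(final_idx) == 0,
    }
    if not final_idx:
        return SelectionResult(dataset=None, retained_ids=(),
                               retained_indices=(), audit=audit)
    filtered = ExposureDataset(
        gene=dataset.gene, cell_type=dataset.cell_type,
        associations=tuple(assocs[i] for i in final_idx))
    return SelectionResult(
        dataset=filtered,
        retained_ids=tuple(assocs[i].variant_id for i in final_idx),
        retained_indices=tuple(final_idx),
        audit=audit,
    )
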
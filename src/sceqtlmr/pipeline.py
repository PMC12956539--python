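"""End-to-end MR pipeline: harmonize, select instruments, Steiger-filter,
estimate, and tier every gene x cell-type pair.

The per-pair flow mirrors the study design: the exposure cis-eQTL set is
harmonized to the outcome GWAS, instruments are selected (p-threshold,
LD clump, F-filter), directionally invalid instruments are removed by
Steiger filtering, and the causal effect is estimated with the Wald ratio
(one instrument), IVW (independent instruments) or LD-aware IVW (when a
correlation matrix is supplied). MR-Egger and the weighted median run as
sensitivity analyses when at least three instruments survive. P-values
are then BH-adjusted per cell type and globally, and each pair receives
its two-level significance tier.

Untestable pairs are never dropped silently: they appear in the result
table with ``method="skipped"`` and a reason, and the audit table keeps
per-stage variant counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .instruments import InstrumentConfig, select_instruments
from .mr import (
    DegenerateInstrumentError,
    MRResult,
    TierConfig,
    assign_tier,
    bh_adjust,
    ivw,
    ivw_correlated,
    mr_egger,
    steiger_filter,
    wald_ratio,
    weighted_median,
)
from .sumstats import EmptyOverlapError, ExposureDataset, HarmonizedSet, harmonize

__all__ = ["MRRunResult", "run_mr"]

RESULT_COLUMNS = [
    "gene", "cell_type", "method", "n_snps", "beta", "se", "pvalue",
    "bh_p_celltype", "bh_p_global", "tier", "egger_beta", "egger_p",
    "egger_intercept_p", "wm_beta", "wm_p", "q_p",
    "steiger_kept", "steiger_removed", "skip_reason",
]


@dataclass(frozen=True)
class MRRunResult:
    """Per-pair result table plus the per-stage audit counts."""

    results: pd.DataFrame
    audit: pd.DataFrame

    def significant(self, tiers: Sequence[str] = ("global", "potential")) -> pd.DataFrame:
        ok = self.results["tier"].isin(tiers)
        return self.results[ok & self.results["beta"].notna()]


def _skip_row(gene: str, cell_type: str, reason: str) -> dict:
    return {
        "gene": gene, "cell_type": cell_type, "method": "skipped",
        "n_snps": 0, "beta": np.nan, "se": np.nan, "pvalue": np.nan,
        "bh_p_celltype": np.nan, "bh_p_global": np.nan, "tier": None,
        "egger_beta": np.nan, "egger_p": np.nan, "egger_intercept_p": np.nan,
        "wm_beta": np.nan, "wm_p": np.nan, "q_p": np.nan,
        "steiger_kept": 0, "steiger_removed": 0, "skip_reason": reason,
    }


def run_mr(exposures: Sequence[ExposureDataset], outcome: pd.DataFrame,
           ld_map: Optional[dict] = None,
           instrument_config: InstrumentConfig = InstrumentConfig(),
           tier_config: TierConfig = TierConfig(),
           palindrome_policy: str = "drop", freq_tolerance: float = 0.08,
           steiger: bool = True, sensitivity: bool = True,
           dispersion: str = "wls", n_boot: int = 1000,
           seed: Optional[int] = None) -> MRRunResult:
    """Run the full MR pipeline over every exposure dataset.

    Parameters
    ----------
    exposures : sequence of ExposureDataset
        One per gene x cell type.
    outcome : DataFrame
        Outcome GWAS summary statistics (standard columns).
    ld_map : dict, optional
        (gene, cell_type) -> LD correlation matrix ordered like the
        exposure associations. When present, clumping uses it and the
        estimator is LD-aware IVW on the retained instruments.
    sensitivity : bool
        Run MR-Egger and the weighted median when k >= 3. ``seed`` is
        then required (weighted-median bootstrap).
    dispersion : str
        IVW dispersion convention, see :func:`sceqtlmr.mr.ivw`.

    Returns
    -------
    MRRunResult
        ``results``: one row per pair (primary estimate plus sensitivity
        columns); ``audit``: per-stage instrument counts.
    """
    rows: list[dict] = []
    audit_rows: list[dict] = []

    for ds in exposures:
        ld = None if ld_map is None else ld_map.get((ds.gene, ds.cell_type))
        audit = {"gene": ds.gene, "cell_type": ds.cell_type,
                 "n_input": len(ds), "n_harmonized": 0, "removed_pvalue": 0,
                 "removed_ld": 0, "removed_weak": 0, "removed_steiger": 0,
                 "n_final": 0, "status": "ok"}
        try:
            h_all = harmonize(ds, outcome, palindrome_policy=palindrome_policy,
                              freq_tolerance=freq_tolerance, ld=ld)
        except EmptyOverlapError:
            audit["status"] = "no overlapping variants"
            audit_rows.append(audit)
            rows.append(_skip_row(ds.gene, ds.cell_type, "no overlapping variants"))
            continue
        audit["n_harmonized"] = h_all.k

        # instrument selection on the harmonized exposure side
        harmonized_ids = set(h_all.variant_ids)
        sub = ExposureDataset(
            gene=ds.gene, cell_type=ds.cell_type,
            associations=tuple(a for a in ds.associations
                               if a.variant_id in harmonized_ids))
        sub_ld = None
        if ld is not None:
            pos = [i for i, a in enumerate(ds.associations)
                   if a.variant_id in harmonized_ids]
            sub_ld = np.asarray(ld, dtype=float)[np.ix_(pos, pos)]
        sel = select_instruments(sub, sub_ld, instrument_config)
        audit.update({k: sel.audit[k] for k in
                      ("removed_pvalue", "removed_ld", "removed_weak")})
        if sel.is_empty:
            audit["status"] = "no instruments after selection"
            audit_rows.append(audit)
            rows.append(_skip_row(ds.gene, ds.cell_type,
                                  "no instruments after selection"))
            continue
        keep = [h_all.variant_ids.index(v) for v in sel.retained_ids]
        h = h_all.subset(keep, reason="not selected as instrument") \
            if len(keep) < h_all.k else h_all

        steiger_removed = 0
        if steiger:
            h_f, report = steiger_filter(h)
            steiger_removed = int((~report["steiger_pass"]).sum())
            audit["removed_steiger"] = steiger_removed
            if h_f is None:
                audit["status"] = "no directionally valid instruments"
                audit_rows.append(audit)
                row = _skip_row(ds.gene, ds.cell_type,
                                "no directionally valid instruments")
                row["steiger_removed"] = steiger_removed
                rows.append(row)
                continue
            h = h_f
        audit["n_final"] = h.k
        audit_rows.append(audit)

        try:
            if h.k == 1:
                primary = wald_ratio(h)
            elif h.ld is not None:
                primary = ivw_correlated(h, dispersion=dispersion)
            else:
                primary = ivw(h, dispersion=dispersion)
        except DegenerateInstrumentError as exc:
            rows.append(_skip_row(ds.gene, ds.cell_type, f"degenerate: {exc}"))
            continue

        row = {
            "gene": ds.gene, "cell_type": ds.cell_type,
            "method": primary.method, "n_snps": primary.n_snps,
            "beta": primary.beta, "se": primary.se, "pvalue": primary.pvalue,
            "bh_p_celltype": np.nan, "bh_p_global": np.nan, "tier": None,
            "egger_beta": np.nan, "egger_p": np.nan,
            "egger_intercept_p": np.nan, "wm_beta": np.nan, "wm_p": np.nan,
            "q_p": primary.q_stat[2] if primary.q_stat else np.nan,
            "steiger_kept": h.k, "steiger_removed": steiger_removed,
            "skip_reason": None,
        }
        if sensitivity and h.k >= 3:
            try:
                egg = mr_egger(h)
                row["egger_beta"] = egg.beta
                row["egger_p"] = egg.pvalue
                row["egger_intercept_p"] = egg.egger_intercept[2]
            except DegenerateInstrumentError:
                pass
            if seed is None:
                raise ValueError("sensitivity analyses need a seed "
                                 "(weighted-median bootstrap)")
            try:
                wm = weighted_median(h, n_boot=n_boot, seed=seed)
                row["wm_beta"] = wm.beta
                row["wm_p"] = wm.pvalue
            except DegenerateInstrumentError:
                pass
        rows.append(row)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = results["pvalue"].notna()
    if tested.any():
        p = results.loc[tested, "pvalue"].to_numpy()
        cts = results.loc[tested, "cell_type"].to_numpy()
        results.loc[tested, "bh_p_global"] = bh_adjust(p, grouping="global")
        results.loc[tested, "bh_p_celltype"] = bh_adjust(
            p, grouping="per_cell_type", groups=cts)
        results.loc[tested, "tier"] = [
            assign_tier(v, tier_config) for v in p]
    return MRRunResult(results=results, audit=pd.DataFrame(audit_rows))
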
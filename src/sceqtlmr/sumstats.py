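"""Summary-statistics containers, I/O, and allele harmonization.

Two-sample Mendelian randomization works entirely on GWAS/eQTL summary
statistics: per-variant effect sizes (beta), standard errors, p-values,
allele frequencies and sample sizes. Before any estimation, the exposure
(cis-eQTL) and outcome (disease GWAS) associations must be aligned to a
common effect allele; a variant whose alleles cannot be reconciled is
dropped with an auditable reason rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "ExposureDataset",
    "HarmonizedSet",
    "SumstatsFormatError",
    "SumstatsValidationError",
    "EmptyOverlapError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
]

REQUIRED_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)
EXPOSURE_COLUMNS = ("gene", "cell_type") + REQUIRED_COLUMNS

_VALID_BASES = frozenset("ACGT")


class SumstatsFormatError(ValueError):
    """File-level problem: missing column, unreadable table."""


class SumstatsValidationError(ValueError):
    """One or more rows violated a field invariant.

    ``errors`` holds (line_number, variant_id, reason) tuples; line numbers
    are 1-based counting the header as line 1.
    """

    def __init__(self, errors: list[tuple[int, str, str]]):
        self.errors = errors
        msgs = "; ".join(f"line {ln} ({vid}): {why}" for ln, vid, why in errors[:10])
        extra = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {msgs}{extra}")


class EmptyOverlapError(ValueError):
    """Exposure and outcome share no variant ids."""


def _check_allele(a: str) -> bool:
    return len(a) >= 1 and set(a.upper()) <= _VALID_BASES


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``;
    ``eaf`` is the effect-allele frequency (may be None when unreported).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self):
        for why, bad in self.validation_problems():
            raise ValueError(f"{self.variant_id}: {why}")

    def validation_problems(self) -> list[tuple[str, bool]]:
        problems = []
        if not (self.se > 0):
            problems.append(("nonpositive SE", True))
        if not (0 < self.pvalue <= 1):
            problems.append(("pvalue outside (0,1]", True))
        if not _check_allele(self.effect_allele) or not _check_allele(self.other_allele):
            problems.append(("allele not an A/C/G/T sequence", True))
        elif self.effect_allele.upper() == self.other_allele.upper():
            problems.append(("effect allele equals other allele", True))
        if self.n < 2:
            problems.append(("sample size < 2", True))
        if self.eaf is not None and not np.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            problems.append(("eaf outside [0,1]", True))
        if self.pos < 1:
            problems.append(("position not 1-based positive", True))
        return problems

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele.upper(), self.other_allele.upper()}
        return pair == {"A", "T"} or pair == {"C", "G"}

    @property
    def zscore(self) -> float:
        return self.beta / self.se


def _validated_row(row: dict) -> tuple[Optional["VariantAssociation"], Optional[str]]:
    """Build a VariantAssociation without raising; return (record, reason)."""
    try:
        eaf = row.get("eaf")
        if eaf is not None and (eaf == "" or (isinstance(eaf, float) and np.isnan(eaf))):
            eaf = None
        rec = VariantAssociation(
            variant_id=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=None if eaf is None else float(eaf),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            n=int(row["n"]),
        )
        return rec, None
    except (ValueError, TypeError) as exc:
        return None, str(exc)


@dataclass(frozen=True)
class ExposureDataset:
    """cis-eQTL associations for one gene in one immune cell type."""

    gene: str
    cell_type: str
    associations: tuple[VariantAssociation, ...]

    def __post_init__(self):
        if len(self.associations) < 1:
            raise ValueError(f"{self.gene}/{self.cell_type}: needs >= 1 association")
        ids = [a.variant_id for a in self.associations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.gene}/{self.cell_type}: duplicate variant ids")

    def __len__(self) -> int:
        return len(self.associations)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(a.variant_id for a in self.associations)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": self.gene, "cell_type": self.cell_type,
                "variant_id": a.variant_id, "chrom": a.chrom, "pos": a.pos,
                "effect_allele": a.effect_allele, "other_allele": a.other_allele,
                "eaf": np.nan if a.eaf is None else a.eaf,
                "beta": a.beta, "se": a.se, "pvalue": a.pvalue, "n": a.n,
            }
            for a in self.associations
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class HarmonizedSet:
    """Exposure/outcome effects aligned to a common effect allele.

    All per-variant vectors share length k >= 1. ``ld`` (optional) is the
    k x k correlation matrix in variant order. ``dropped`` records every
    variant excluded during harmonization as (variant_id, reason).
    """

    gene: str
    cell_type: str
    variant_ids: tuple[str, ...]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    n_exp: int
    n_out: int
    effect_allele: tuple[str, ...] = ()
    other_allele: tuple[str, ...] = ()
    pval_exp: Optional[np.ndarray] = None
    pval_out: Optional[np.ndarray] = None
    ld: Optional[np.ndarray] = None
    dropped: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        k = len(self.variant_ids)
        if k < 1:
            raise ValueError("harmonized set needs k >= 1 variants")
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (k,):
                raise ValueError(f"{name} has shape {v.shape}, expected ({k},)")
        if not (np.all(self.se_exp > 0) and np.all(self.se_out > 0)):
            raise ValueError("standard errors must be positive")
        if self.ld is not None:
            R = np.asarray(self.ld, dtype=float)
            object.__setattr__(self, "ld", R)
            if R.shape != (k, k):
                raise ValueError(f"ld has shape {R.shape}, expected ({k},{k})")
            if not np.allclose(R, R.T, atol=1e-8):
                raise ValueError("ld matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-8):
                raise ValueError("ld matrix must have unit diagonal")
            if np.any(np.abs(R) > 1 + 1e-8):
                raise ValueError("ld entries must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: Sequence[int], reason: str = "filtered") -> "HarmonizedSet":
        """Restrict to the variants at positions ``keep`` (order preserved);
        removed variants are appended to ``dropped`` with ``reason``."""
        keep = list(keep)
        if len(keep) < 1:
            raise ValueError("subset would be empty; handle upstream")
        removed = [i for i in range(self.k) if i not in set(keep)]
        idx = np.asarray(keep, dtype=int)
        return replace(
            self,
            variant_ids=tuple(self.variant_ids[i] for i in keep),
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            effect_allele=tuple(self.effect_allele[i] for i in keep) if self.effect_allele else (),
            other_allele=tuple(self.other_allele[i] for i in keep) if self.other_allele else (),
            pval_exp=None if self.pval_exp is None else self.pval_exp[idx],
            pval_out=None if self.pval_out is None else self.pval_out[idx],
            ld=None if self.ld is None else self.ld[np.ix_(idx, idx)],
            dropped=self.dropped
            + tuple((self.variant_ids[i], reason) for i in removed),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene": self.gene, "cell_type": self.cell_type,
            "variant_id": list(self.variant_ids),
            "beta_exp": self.beta_exp, "se_exp": self.se_exp,
            "beta_out": self.beta_out, "se_out": self.se_out,
        })
        if self.effect_allele:
            df["effect_allele"] = list(self.effect_allele)
            df["other_allele"] = list(self.other_allele)
        return df

    def dropped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["variant_id", "reason"])


# ---------------------------------------------------------------------------
# I/O


def _resolve_columns(df: pd.DataFrame, required: Sequence[str],
                     columns: Optional[dict]) -> pd.DataFrame:
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_sumstats(path: Union[str, Path], role: str,
                  columns: Optional[dict] = None):
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header; ``.gz`` accepted (pandas infers).
    role : {"exposure", "outcome"}
        Exposure files carry ``gene`` and ``cell_type`` columns and are
        returned as a list of :class:`ExposureDataset` (one per gene x
        cell type). Outcome files are returned as a validated DataFrame.
    columns : dict, optional
        Mapping from canonical names to the file's column names, e.g.
        ``{"variant_id": "SNP"}``.

    Raises
    ------
    SumstatsFormatError
        Missing required columns.
    SumstatsValidationError
        Any row violating a field invariant (all offenders are collected
        and reported with line numbers before raising).
    """
    if role not in ("exposure", "outcome"):
        raise ValueError("role must be 'exposure' or 'outcome'")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = EXPOSURE_COLUMNS if role == "exposure" else REQUIRED_COLUMNS
    df = _resolve_columns(df, required, columns)

    records: list[tuple[int, dict, VariantAssociation]] = []
    errors: list[tuple[int, str, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        rec, reason = _validated_row(row)
        if rec is None:
            errors.append((line, str(row.get("variant_id", "?")), reason))
        else:
            records.append((line, row, rec))
    if errors:
        raise SumstatsValidationError(errors)

    if role == "outcome":
        out = pd.DataFrame([
            {
                "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta, "se": r.se, "pvalue": r.pvalue, "n": r.n,
            }
            for _, _, r in records
        ])
        if out["variant_id"].duplicated().any():
            dups = out.loc[out["variant_id"].duplicated(), "variant_id"].tolist()
            raise SumstatsValidationError(
                [(0, d, "duplicate variant_id in outcome") for d in dups])
        return out

    grouped: dict[tuple[str, str], list[VariantAssociation]] = {}
    for _, row, rec in records:
        grouped.setdefault((str(row["gene"]), str(row["cell_type"])), []).append(rec)
    return [
        ExposureDataset(gene=g, cell_type=ct, associations=tuple(assocs))
        for (g, ct), assocs in grouped.items()
    ]


def write_sumstats(data, path: Union[str, Path]) -> None:
    """Write exposure datasets or an outcome table as TSV (6 significant
    digits for floats, the package-wide output precision)."""
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = pd.concat([d.to_frame() for d in data], ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Harmonization


def _classify(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str:
    if ea_x == ea_y and oa_x == oa_y:
        return "match"
    if ea_x == oa_y and oa_x == ea_y:
        return "swap"
    return "mismatch"


def harmonize(exposure: ExposureDataset, outcome: pd.DataFrame,
              palindrome_policy: str = "drop", freq_tolerance: float = 0.08,
              ld: Optional[np.ndarray] = None) -> HarmonizedSet:
    """Align outcome associations to the exposure effect allele.

    For each variant present in both datasets: matching allele pairs are
    kept as-is; swapped pairs have the outcome beta negated and eaf
    reflected (1 - eaf); irreconcilable pairs are dropped. Palindromic
    variants (A/T or C/G) are strand-ambiguous and handled per
    ``palindrome_policy``:

    - ``"drop"``: always dropped;
    - ``"freq"``: oriented by allele frequency when both eafs are outside
      ``[0.5 - freq_tolerance, 0.5 + freq_tolerance]`` (same side of 0.5
      means the nominal alignment stands, opposite sides means a hidden
      strand flip, so the outcome effect is negated); otherwise dropped
      as an ambiguous palindrome.

    No strand-complement rescue is attempted for non-palindromic variants:
    both datasets are assumed reported on the same strand, so e.g. A/G vs
    C/T at one id is a mismatch, not a flip.

    ``ld``, when given, must be ordered like ``exposure.associations``;
    the retained submatrix is carried into the result.

    Raises
    ------
    EmptyOverlapError
        If no variant survives (including zero shared ids).
    """
    if palindrome_policy not in ("drop", "freq"):
        raise ValueError("palindrome_policy must be 'drop' or 'freq'")
    out_by_id = {str(r["variant_id"]): r for r in outcome.to_dict("records")}
    if len(out_by_id) != len(outcome):
        raise ValueError("outcome variant ids are not unique")
    if ld is not None:
        ld = np.asarray(ld, dtype=float)
        if ld.shape != (len(exposure), len(exposure)):
            raise ValueError("ld shape does not match exposure associations")

    kept_idx: list[int] = []
    kept: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for i, a in enumerate(exposure.associations):
        row = out_by_id.get(a.variant_id)
        if row is None:
            dropped.append((a.variant_id, "missing in outcome"))
            continue
        ea_y, oa_y = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        rel = _classify(a.effect_allele, a.other_allele, ea_y, oa_y)
        if rel == "mismatch":
            dropped.append((a.variant_id, "allele mismatch"))
            continue
        beta_y = float(row["beta"])
        eaf_y = row.get("eaf")
        eaf_y = None if eaf_y is None or (isinstance(eaf_y, float) and np.isnan(eaf_y)) else float(eaf_y)
        if rel == "swap":
            beta_y = -beta_y
            eaf_y = None if eaf_y is None else 1.0 - eaf_y
        if a.is_palindromic:
            if palindrome_policy == "drop":
                dropped.append((a.variant_id, "palindromic (policy=drop)"))
                continue
            lo, hi = 0.5 - freq_tolerance, 0.5 + freq_tolerance
            eaf_x = a.eaf
            informative = (
                eaf_x is not None and eaf_y is not None
                and not (lo <= eaf_x <= hi) and not (lo <= eaf_y <= hi)
            )
            if not informative:
                dropped.append((a.variant_id, "ambiguous palindrome"))
                continue
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:  # hidden strand flip
                beta_y = -beta_y
        kept_idx.append(i)
        kept.append({
            "variant_id": a.variant_id,
            "effect_allele": a.effect_allele, "other_allele": a.other_allele,
            "beta_exp": a.beta, "se_exp": a.se, "pval_exp": a.pvalue,
            "beta_out": beta_y, "se_out": float(row["se"]),
            "pval_out": float(row["pvalue"]), "n_out": int(row["n"]),
        })

    if not kept:
        raise EmptyOverlapError(
            f"{exposure.gene}/{exposure.cell_type}: no harmonizable variants "
            f"({len(dropped)} dropped)")

    idx = np.asarray(kept_idx, dtype=int)
    return HarmonizedSet(
        gene=exposure.gene,
        cell_type=exposure.cell_type,
        variant_ids=tuple(r["variant_id"] for r in kept),
        beta_exp=np.array([r["beta_exp"] for r in kept]),
        se_exp=np.array([r["se_exp"] for r in kept]),
        beta_out=np.array([r["beta_out"] for r in kept]),
        se_out=np.array([r["se_out"] for r in kept]),
        n_exp=int(np.median([a.n for a in exposure.associations])),
        n_out=int(np.median([r["n_out"] for r in kept])),
        effect_allele=tuple(r["effect_allele"] for r in kept),
        other_allele=tuple(r["other_allele"] for r in kept),
        pval_exp=np.array([r["pval_exp"] for r in kept]),
        pval_out=np.array([r["pval_out"] for r in kept]),
        ld=None if ld is None else ld[np.ix_(idx, idx)],
        dropped=tuple(dropped),
    )
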
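"""Odds-ratio conversion, multiple-testing correction, and report assembly.

Causal estimates on the log-odds scale are exponentiated to odds ratios with
normal-approximation 95% CIs.  Across exposures tested against one outcome,
primary p-values are adjusted by the Benjamini–Hochberg step-up procedure;
raw p < 0.05 that does not survive the correction is labelled "suggestive".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import math

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .estimators import MREstimate

__all__ = [
    "ResultRow",
    "to_odds_ratio",
    "se_from_or_pval",
    "bh_fdr",
    "build_report",
    "Z_95",
]

Z_95 = float(norm.ppf(0.975))


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, CI low, CI high).

    CI = exp(θ ± z₀.₉₇₅·σ); bounds satisfy lo·hi = OR² (log symmetry).
    A NaN SE (point-only estimates) yields NaN bounds.
    """
    or_ = math.exp(est.theta)
    if math.isnan(est.se):
        return or_, float("nan"), float("nan")
    half = Z_95 * est.se
    return or_, math.exp(est.theta - half), math.exp(est.theta + half)


def se_from_or_pval(or_: float, pval: float) -> float:
    """Recover the log-scale SE implied by a published (OR, two-sided P) pair.

    se = |ln OR| / Φ⁻¹(1 − P/2); useful for reconstructing CIs from printed
    results tables.
    """
    if or_ <= 0.0:
        raise ValidationError("odds ratio must be positive")
    if not (0.0 < pval < 1.0):
        raise ValidationError("p-value must lie in (0, 1) for SE reconstruction")
    return float(abs(math.log(or_)) / norm.ppf(1.0 - pval / 2.0))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{k ≥ i} p_(k)·m/k, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ResultRow:
    """One (exposure, outcome, method) line of the final results table."""

    exposure: str
    outcome: str
    method: str
    n_snp: int
    theta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    is_primary: bool = True
    fdr_pval: Optional[float] = None
    significance: Optional[str] = None

    @classmethod
    def from_estimate(cls, exposure: str, outcome: str, est: MREstimate,
                      is_primary: bool = True) -> "ResultRow":
        or_, lo, hi = to_odds_ratio(est)
        return cls(
            exposure=exposure, outcome=outcome, method=est.method,
            n_snp=est.n_snp, theta=est.theta, se=est.se,
            or_=or_, ci_low=lo, ci_high=hi, pval=est.pval,
            is_primary=is_primary,
        )


def _label(row: ResultRow) -> str:
    if not (row.pval < 0.05):
        return "ns"
    if row.fdr_pval is not None and row.fdr_pval < 0.05:
        return "significant"
    return "suggestive"


def apply_family_fdr(rows: list[ResultRow]) -> list[ResultRow]:
    """BH-adjust primary p-values within each outcome's family of exposures.

    The family is the set of primary rows sharing an outcome (m = number of
    exposures); sensitivity rows are labelled but not adjusted.  A family of
    one passes its p-value through unchanged.
    """
    by_outcome: dict[str, list[ResultRow]] = {}
    for row in rows:
        if row.is_primary:
            by_outcome.setdefault(row.outcome, []).append(row)
    for family in by_outcome.values():
        adjusted = bh_fdr([r.pval for r in family])
        for row, fdr in zip(family, adjusted):
            row.fdr_pval = float(fdr)
    for row in rows:
        row.significance = _label(row)
    return rows


def build_report(
    rows: list[ResultRow],
    outdir,
    meta: Optional[dict] = None,
) -> dict[str, Path]:
    """Write results.tsv, results.json (nested outcome→exposure→method), and
    run_meta.json.  FDR is applied to primary rows per outcome family before
    writing; machine outputs carry full precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = apply_family_fdr(rows)

    frame = pd.DataFrame(
        [
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "method": r.method,
                "n_snp": r.n_snp,
                "theta": r.theta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pval": r.pval,
                "fdr_pval": r.fdr_pval,
                "role": "primary" if r.is_primary else "sensitivity",
                "significance": r.significance,
            }
            for r in rows
        ]
    )
    tsv_path = outdir / "results.tsv"
    frame.to_csv(tsv_path, sep="\t", index=False)

    nested: dict = {}
    for r in rows:
        nested.setdefault(r.outcome, {}).setdefault(r.exposure, {})[r.method] = {
            "n_snp": r.n_snp,
            "theta": r.theta,
            "se": r.se,
            "or": r.or_,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pval": r.pval,
            "fdr_pval": r.fdr_pval,
            "significance": r.significance,
        }
    json_path = outdir / "results.json"
    json_path.write_text(json.dumps(nested, indent=2, allow_nan=True) + "\n")

    meta_path = outdir / "run_meta.json"
    meta_path.write_text(json.dumps(meta or {}, indent=2, default=str) + "\n")
    return {"tsv": tsv_path, "json": json_path, "meta": meta_path}
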
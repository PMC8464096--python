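"""Heterogeneity and pleiotropy diagnostics, plus per-SNP audit tables.

Cochran's Q tests whether the per-instrument Wald ratios are mutually
consistent (chi-square with J−1 df under homogeneity); the single-SNP and
leave-one-out tables are the data behind forest and leave-one-out plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._errors import InsufficientInstrumentsError
from .estimators import MREstimate, ivw, wald_ratio
from .harmonize import HarmonizedInstrument
from .inference_report import to_odds_ratio

__all__ = [
    "HeterogeneityReport",
    "cochran_q",
    "leave_one_out",
    "single_snp_table",
]


@dataclass
class HeterogeneityReport:
    """Heterogeneity/pleiotropy diagnostics for one exposure–outcome pair."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: Optional[MREstimate] = None
    i2gx: Optional[float] = None
    presso_global_p: Optional[float] = None

    def to_dict(self) -> dict:
        out = {"cochran_q": self.q, "q_df": self.q_df, "q_pval": self.q_pval}
        if self.egger_intercept is not None:
            out["egger_intercept"] = self.egger_intercept.theta
            out["egger_intercept_se"] = self.egger_intercept.se
            out["egger_intercept_pval"] = self.egger_intercept.pval
        if self.i2gx is not None:
            out["i2gx"] = self.i2gx
        if self.presso_global_p is not None:
            out["presso_global_p"] = self.presso_global_p
        return out


def cochran_q(
    hs: Sequence[HarmonizedInstrument], theta_ref: MREstimate
) -> tuple[float, int, float]:
    """Cochran's Q around the IVW estimate.

    Q = Σ w_j (θ̂_j − θ_IVW)² with first-order ratio weights
    w_j = β̂_Xj²/σ_Yj²; upper-tail chi-square(J−1) p-value.
    """
    if len(hs) < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 instruments")
    bx = np.array([h.beta_x for h in hs])
    by = np.array([h.beta_y for h in hs])
    sy = np.array([h.se_y for h in hs])
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - theta_ref.theta) ** 2))
    df = len(hs) - 1
    return q, df, float(chi2.sf(q, df))


def leave_one_out(hs: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Leave-one-out IVW table: one refit per excluded instrument.

    Rows follow instrument order; a final row with ``excluded_snp = "(none)"``
    carries the all-instrument fit.
    """
    if len(hs) < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 instruments")
    rows = []
    for i, h in enumerate(hs):
        rest = [other for j, other in enumerate(hs) if j != i]
        est = ivw(rest) if len(rest) >= 2 else wald_ratio(rest[0])
        rows.append(_loo_row(h.snp_id, est))
    rows.append(_loo_row("(none)", ivw(hs)))
    return pd.DataFrame(rows)


def _loo_row(label: str, est: MREstimate) -> dict:
    or_, lo, hi = to_odds_ratio(est)
    return {
        "excluded_snp": label,
        "theta": est.theta,
        "se": est.se,
        "pval": est.pval,
        "n_snp": est.n_snp,
        "or": or_,
        "ci_low": lo,
        "ci_high": hi,
    }


def single_snp_table(hs: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP Wald estimates with OR and CI columns (forest-plot data)."""
    if len(hs) < 1:
        raise InsufficientInstrumentsError("single_snp_table requires >= 1 instrument")
    rows = []
    for h in hs:
        est = wald_ratio(h)
        or_, lo, hi = to_odds_ratio(est)
        rows.append(
            {
                "snp_id": h.snp_id,
                "theta": est.theta,
                "se": est.se,
                "pval": est.pval,
                "or": or_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
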
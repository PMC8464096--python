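"""Allele harmonization of exposure and outcome summary statistics.

Both studies must report effects on the *same* allele before any ratio of the
two is meaningful.  Harmonization resolves three nuisances: (i) the studies
may label the allele pair in opposite orientation (effect/other swapped), in
which case the outcome effect is negated; (ii) the studies may report on
opposite DNA strands, fixed by complementing the outcome alleles; and (iii)
palindromic variants (A/T or C/G), where strand is undecidable from alleles
alone and allele frequency must arbitrate — variants whose minor-allele
frequency approaches 0.5 (above 0.42 in either study) are discarded as
unresolvable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._errors import MrpipeError
from .instruments import InstrumentSet
from .sumstats_io import GwasRecord, SumStatsTable

__all__ = [
    "HarmonizedInstrument",
    "HarmonizeResult",
    "classify_palindromic",
    "harmonize_pair",
    "harmonize_set",
    "read_harmonized",
    "write_harmonized",
    "DEFAULT_PALINDROME_MAF_MAX",
]

DEFAULT_PALINDROME_MAF_MAX = 0.42

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUS_ALIGNED = "aligned"
STATUS_FLIPPED = "flipped"
STATUS_STRAND = "strand_corrected"
STATUS_DROPPED = "dropped"


@dataclass
class HarmonizedInstrument:
    """A SNP's exposure/outcome effects expressed on one shared effect allele."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: Optional[float]
    eaf_y: Optional[float]
    status: str
    reason: Optional[str] = None  # machine-readable drop reason

    @property
    def dropped(self) -> bool:
        return self.status == STATUS_DROPPED


@dataclass
class HarmonizeResult:
    """Kept and dropped instruments; |kept| + |dropped| = |input|."""

    kept: list[HarmonizedInstrument]
    dropped: list[HarmonizedInstrument]

    def drop_summary(self) -> dict[str, int]:
        summary: dict[str, int] = {}
        for h in self.dropped:
            summary[h.reason] = summary.get(h.reason, 0) + 1
        return summary


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _dropped(exp: GwasRecord, out: GwasRecord, reason: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_x=exp.beta, se_x=exp.se,
        beta_y=out.beta, se_y=out.se,
        eaf_x=exp.eaf, eaf_y=out.eaf,
        status=STATUS_DROPPED, reason=reason,
    )


def _result(exp: GwasRecord, out: GwasRecord, beta_y: float,
            eaf_y: Optional[float], status: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_x=exp.beta, se_x=exp.se,
        beta_y=beta_y, se_y=out.se,
        eaf_x=exp.eaf, eaf_y=eaf_y,
        status=status,
    )


def harmonize_pair(
    exp: GwasRecord,
    out: GwasRecord,
    palindrome_maf_max: float = DEFAULT_PALINDROME_MAF_MAX,
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure record's effect allele.

    Same pair, same orientation → ``aligned`` (betas unchanged); same pair in
    swapped orientation → ``flipped`` (beta_y negated, eaf_y complemented);
    pair matching after strand complementation → ``strand_corrected``;
    palindromic pairs are oriented by allele frequency or dropped when the
    MAF exceeds ``palindrome_maf_max`` in *either* study (or when eaf is
    missing); anything else is dropped as an allele mismatch.
    """
    if exp.snp_id != out.snp_id:
        raise MrpipeError(
            f"harmonize_pair called on different SNPs: {exp.snp_id} vs {out.snp_id}"
        )
    exp_pair = {exp.effect_allele, exp.other_allele}
    out_pair = {out.effect_allele, out.other_allele}

    if classify_palindromic(exp.effect_allele, exp.other_allele):
        if out_pair != exp_pair:
            return _dropped(exp, out, "allele_mismatch")
        if exp.eaf is None or out.eaf is None:
            return _dropped(exp, out, "palindromic_no_eaf")
        maf_x = min(exp.eaf, 1.0 - exp.eaf)
        maf_y = min(out.eaf, 1.0 - out.eaf)
        if maf_x > palindrome_maf_max or maf_y > palindrome_maf_max:
            return _dropped(exp, out, "palindromic_ambiguous")
        # Allele labels cannot fix the strand; frequency does.  The outcome's
        # reported effect allele is taken to be the exposure's effect allele
        # iff both frequencies fall on the same side of 0.5.
        if (exp.eaf < 0.5) == (out.eaf < 0.5):
            return _result(exp, out, out.beta, out.eaf, STATUS_ALIGNED)
        return _result(exp, out, -out.beta, 1.0 - out.eaf, STATUS_FLIPPED)

    if out_pair == exp_pair:
        if out.effect_allele == exp.effect_allele:
            return _result(exp, out, out.beta, out.eaf, STATUS_ALIGNED)
        eaf_y = None if out.eaf is None else 1.0 - out.eaf
        return _result(exp, out, -out.beta, eaf_y, STATUS_FLIPPED)

    comp_effect = _COMPLEMENT[out.effect_allele]
    comp_other = _COMPLEMENT[out.other_allele]
    if {comp_effect, comp_other} == exp_pair:
        if comp_effect == exp.effect_allele:
            return _result(exp, out, out.beta, out.eaf, STATUS_STRAND)
        eaf_y = None if out.eaf is None else 1.0 - out.eaf
        return _result(exp, out, -out.beta, eaf_y, STATUS_STRAND)

    return _dropped(exp, out, "allele_mismatch")


def _harmonize_proxy(
    exp: GwasRecord,
    proxy: GwasRecord,
    eaf_tolerance: float = 0.02,
) -> HarmonizedInstrument:
    """Harmonize an instrument against a *different* SNP serving as proxy.

    Without phase information the proxy's effect allele is chosen as the one
    whose frequency matches the instrument's effect-allele frequency
    (positive-LD assumption).  When the two candidate orientations are not
    distinguishable by frequency (difference below ``eaf_tolerance``), the
    pair is dropped as phase-unknown.
    """
    if exp.eaf is None or proxy.eaf is None:
        return _dropped(exp, proxy, "proxy_phase_unknown")
    direct = abs(proxy.eaf - exp.eaf)
    swapped = abs((1.0 - proxy.eaf) - exp.eaf)
    if abs(direct - swapped) < eaf_tolerance:
        return _dropped(exp, proxy, "proxy_phase_unknown")
    if direct < swapped:
        harmonized = _result(exp, proxy, proxy.beta, proxy.eaf, STATUS_ALIGNED)
    else:
        harmonized = _result(exp, proxy, -proxy.beta, 1.0 - proxy.eaf, STATUS_FLIPPED)
    harmonized.snp_id = exp.snp_id
    return harmonized


def write_harmonized(hs: list[HarmonizedInstrument], path) -> None:
    """Write harmonized instruments as a tab-delimited table (full precision)."""
    from pathlib import Path

    lines = ["snp_id\tbeta_x\tse_x\tbeta_y\tse_y\teaf_x\teaf_y\tstatus\treason"]
    for h in hs:
        lines.append("\t".join((
            h.snp_id, repr(h.beta_x), repr(h.se_x), repr(h.beta_y), repr(h.se_y),
            "NA" if h.eaf_x is None else repr(h.eaf_x),
            "NA" if h.eaf_y is None else repr(h.eaf_y),
            h.status, h.reason or "",
        )))
    Path(path).write_text("\n".join(lines) + "\n")


def read_harmonized(path) -> list[HarmonizedInstrument]:
    """Read a table written by :func:`write_harmonized`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"snp_id": str}, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        out.append(HarmonizedInstrument(
            snp_id=row.snp_id,
            beta_x=float(row.beta_x), se_x=float(row.se_x),
            beta_y=float(row.beta_y), se_y=float(row.se_y),
            eaf_x=None if row.eaf_x == "NA" else float(row.eaf_x),
            eaf_y=None if row.eaf_y == "NA" else float(row.eaf_y),
            status=row.status,
            reason=row.reason or None,
        ))
    return out


def harmonize_set(
    instruments: InstrumentSet,
    outcome: SumStatsTable,
    palindrome_maf_max: float = DEFAULT_PALINDROME_MAF_MAX,
) -> HarmonizeResult:
    """Harmonize every instrument against the outcome table, preserving order.

    Proxied instruments (per the set's provenance) are matched to the proxy's
    outcome record and oriented by allele frequency.  Instruments missing from
    the outcome with no proxy are dropped with reason ``missing_in_outcome``.
    """
    kept: list[HarmonizedInstrument] = []
    dropped: list[HarmonizedInstrument] = []
    for record in instruments.snps:
        provenance = instruments.provenance.get(record.snp_id)
        if provenance is not None and provenance.kind == "proxy":
            proxy_record = outcome.get(provenance.original_id)
            if proxy_record is None:
                harmonized = _dropped(record, record, "missing_in_outcome")
            else:
                harmonized = _harmonize_proxy(record, proxy_record)
        else:
            out_record = outcome.get(record.snp_id)
            if out_record is None:
                harmonized = _dropped(record, record, "missing_in_outcome")
            else:
                harmonized = harmonize_pair(record, out_record, palindrome_maf_max)
        (dropped if harmonized.dropped else kept).append(harmonized)
    return HarmonizeResult(kept=kept, dropped=dropped)
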
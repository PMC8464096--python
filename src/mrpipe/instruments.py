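"""Instrument selection, proxy substitution, and instrument-strength statistics.

Instruments are genome-wide-significant (p < 5e-8), common (MAF > 0.01),
approximately independent variants selected by greedy LD clumping
(r² > 0.05 within 1000 kb prunes the weaker association).  Instruments absent
from the outcome study can be replaced by a proxy in high LD (r² ≥ 0.8).
Per-SNP strength is summarized by the F-statistic (beta/se)², with F ≤ 10
flagged as weak, and by the variance explained R² = F/(F + n − 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.stats import norm

from ._errors import ValidationError
from .sumstats_io import GwasRecord, LdTable, SumStatsTable

__all__ = [
    "Provenance",
    "InstrumentSet",
    "StrengthReport",
    "PowerInput",
    "filter_significant",
    "clump_greedy",
    "find_proxies",
    "apply_proxies",
    "instrument_strength",
    "power_binary_outcome",
]

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_MAF_MIN = 0.01
DEFAULT_CLUMP_R2 = 0.05
DEFAULT_CLUMP_KB = 1000.0
DEFAULT_PROXY_R2 = 0.8
WEAK_F_THRESHOLD = 10.0


@dataclass
class Provenance:
    """How an instrument entered the set: selected directly or via a proxy."""

    kind: str  # "original" | "proxy"
    original_id: Optional[str] = None
    r2: Optional[float] = None


@dataclass
class InstrumentSet:
    """An ordered set of exposure instruments with per-SNP provenance."""

    exposure_label: str
    snps: list[GwasRecord] = field(default_factory=list)
    provenance: dict[str, Provenance] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def ids(self) -> list[str]:
        return [r.snp_id for r in self.snps]


@dataclass
class StrengthReport:
    """Per-instrument F-statistics, weak-instrument flags, and total R²."""

    per_snp_F: dict[str, float]
    per_snp_R2: dict[str, float]
    total_R2: float
    weak_flags: dict[str, bool]


@dataclass
class PowerInput:
    """Inputs to the binary-outcome power approximation."""

    alpha: float
    n_outcome: int
    case_fraction: float
    r2_exposure: float
    or_alt: float

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_outcome < 1:
            raise ValidationError("n_outcome must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not (0.0 <= self.r2_exposure < 1.0):
            raise ValidationError("r2_exposure must lie in [0, 1)")
        if self.or_alt <= 0.0:
            raise ValidationError("or_alt must be positive")


def filter_significant(
    table: SumStatsTable,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    maf_min: float = DEFAULT_MAF_MIN,
) -> SumStatsTable:
    """Keep genome-wide-significant, common variants.

    Retains records with ``pval < p_threshold`` (strict) and
    ``min(eaf, 1−eaf) > maf_min``.  Records with missing eaf pass the MAF
    filter at this stage but their ids are recorded under
    ``result.notes["eaf_missing"]``; the palindrome rule downstream decides
    their fate.
    """
    kept: list[GwasRecord] = []
    eaf_missing: list[str] = []
    for record in table.records:
        if not (record.pval < p_threshold):
            continue
        if record.eaf is None:
            eaf_missing.append(record.snp_id)
        elif not (record.maf > maf_min):
            continue
        kept.append(record)
    result = table.subset([r.snp_id for r in kept])
    result.notes["eaf_missing"] = eaf_missing
    return result


def clump_greedy(
    candidates: SumStatsTable,
    ld: LdTable,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
) -> InstrumentSet:
    """Greedy p-value-ordered LD clumping.

    Candidates are visited in order of ascending p (ties by chromosome,
    position, then snp_id, so the result is independent of input row order).
    Each accepted SNP removes every remaining same-chromosome SNP within
    ``window_kb`` whose r² with it is either known to exceed ``r2_max`` or is
    *unknown* — the conservative rule: a local LD table cannot certify
    independence it has no entry for.  Cross-chromosome and out-of-window
    pairs are never pruned.
    """
    window_bp = window_kb * 1000.0
    remaining = sorted(
        candidates.records, key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id)
    )
    accepted: list[GwasRecord] = []
    while remaining:
        best = remaining.pop(0)
        accepted.append(best)
        survivors = []
        for other in remaining:
            if other.chrom == best.chrom and abs(other.pos - best.pos) <= window_bp:
                r2 = ld.lookup(best.snp_id, other.snp_id)
                if r2 is LdTable.UNKNOWN or r2 > r2_max:
                    continue  # pruned
            survivors.append(other)
        remaining = survivors
    return InstrumentSet(
        exposure_label=candidates.study_label,
        snps=accepted,
        provenance={r.snp_id: Provenance("original") for r in accepted},
    )


def find_proxies(
    missing: list[str],
    outcome: SumStatsTable,
    ld: LdTable,
    r2_min: float = DEFAULT_PROXY_R2,
) -> tuple[dict[str, tuple[str, float]], list[str]]:
    """Find outcome-present proxies for instruments absent from the outcome.

    For each missing instrument, returns the outcome SNP with the highest
    known r² ≥ ``r2_min`` (ties by lexicographically smallest snp_id).
    Returns ``(mapping original → (proxy, r2), dropped ids)``.
    """
    mapping: dict[str, tuple[str, float]] = {}
    dropped: list[str] = []
    for snp_id in missing:
        candidates = [
            (other, r2)
            for other, r2 in ld.neighbors(snp_id).items()
            if other in outcome and r2 >= r2_min
        ]
        if not candidates:
            dropped.append(snp_id)
            continue
        best = min(candidates, key=lambda item: (-item[1], item[0]))
        mapping[snp_id] = best
    return mapping, dropped


def apply_proxies(
    instruments: InstrumentSet,
    outcome: SumStatsTable,
    ld: LdTable,
    r2_min: float = DEFAULT_PROXY_R2,
) -> InstrumentSet:
    """Substitute proxies for instruments missing from the outcome table.

    Instruments present in the outcome are kept unchanged; missing ones are
    proxied when a neighbor with known r² ≥ ``r2_min`` exists in the outcome,
    otherwise dropped (and reported on ``result.dropped``).
    """
    missing = [snp_id for snp_id in instruments.ids() if snp_id not in outcome]
    mapping, unproxied = find_proxies(missing, outcome, ld, r2_min)
    snps: list[GwasRecord] = []
    provenance: dict[str, Provenance] = {}
    dropped = list(instruments.dropped)
    for record in instruments.snps:
        if record.snp_id in outcome:
            snps.append(record)
            provenance[record.snp_id] = instruments.provenance.get(
                record.snp_id, Provenance("original")
            )
        elif record.snp_id in mapping:
            proxy_id, r2 = mapping[record.snp_id]
            snps.append(record)  # exposure stats stay those of the instrument
            provenance[record.snp_id] = Provenance("proxy", original_id=proxy_id, r2=r2)
        else:
            dropped.append((record.snp_id, "no_proxy_at_threshold"))
    return InstrumentSet(
        exposure_label=instruments.exposure_label,
        snps=snps,
        provenance=provenance,
        dropped=dropped,
    )


def instrument_strength(instruments: InstrumentSet, n_exposure: int) -> StrengthReport:
    """F-statistics and variance explained from summary data.

    Per SNP, F = (beta/se)² and R² = F/(F + n − 2); the total R² sums per-SNP
    contributions, which is adequate after clumping to near-independence.
    SNPs with F ≤ 10 are flagged weak.
    """
    if n_exposure <= 2:
        raise ValidationError("n_exposure must exceed 2")
    per_f: dict[str, float] = {}
    per_r2: dict[str, float] = {}
    weak: dict[str, bool] = {}
    for record in instruments.snps:
        f_stat = (record.beta / record.se) ** 2
        per_f[record.snp_id] = f_stat
        per_r2[record.snp_id] = f_stat / (f_stat + n_exposure - 2)
        weak[record.snp_id] = f_stat <= WEAK_F_THRESHOLD
    return StrengthReport(
        per_snp_F=per_f,
        per_snp_R2=per_r2,
        total_R2=sum(per_r2.values()),
        weak_flags=weak,
    )


def power_binary_outcome(inp: PowerInput) -> float:
    """Approximate power of a two-sample MR test with a binary outcome.

    Uses the summary-data normal approximation
    ``power = Φ(|ln OR| · sqrt(n · R² · φ(1−φ)) − z_{1−α/2})``
    with φ the outcome case fraction and R² the variance in the exposure
    explained by the instruments.  Monotone increasing in n, R², and |ln OR|.
    """
    inp.validate()
    ncp = abs(math.log(inp.or_alt)) * math.sqrt(
        inp.n_outcome
        * inp.r2_exposure
        * inp.case_fraction
        * (1.0 - inp.case_fraction)
    )
    return float(norm.cdf(ncp - norm.ppf(1.0 - inp.alpha / 2.0)))
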
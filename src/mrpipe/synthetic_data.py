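"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of self-reported-infection and
Alzheimer's-disease case–control GWAS: a handful of genome-wide-significant
instruments (1–15 per exposure) embedded among null SNPs and local LD
satellites, with binary-trait log-odds effect sizes, realistic standard
errors from the allele-frequency/sample-size approximation

    se ≈ 1 / sqrt(2·maf·(1−maf)·n·φ·(1−φ)),   φ = case fraction,

and the allele/strand nuisances (palindromic pairs, swapped allele order,
opposite-strand reporting) that harmonization must resolve.

Generative model (the InSIDE structure under which IVW and Egger are
derived): observed β̂_Xj ~ N(β_Xj, σ_Xj) and β̂_Yj ~ N(θ·β_Xj + α_j, σ_Yj),
with direct effects α_j ~ N(μ_α, σ_α²) drawn independently of instrument
strength.  Effect alleles are defined as the exposure-risk-increasing
alleles, so directional pleiotropy (μ_α ≠ 0) has a well-defined sign.

Instrument true effects are drawn to an F-statistic in ``f_range`` and the
observed exposure effect is redrawn until genome-wide-significant
(p < 5e-8), so instrument selection recovers exactly the planted instruments
in clean scenarios; at the default strength (F ≥ 60) the redraw probability
is ~1% for the weakest instruments and the induced winner's-curse bias on
the causal estimate is far below the sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import ValidationError
from .harmonize import HarmonizedInstrument
from .sumstats_io import GwasRecord, LdTable, SumStatsTable

__all__ = [
    "SimConfig",
    "OutcomeSpec",
    "StudyPreset",
    "SimTruth",
    "StudyData",
    "simulate_two_sample",
    "simulate_study",
    "simulate_harmonized",
    "scenario_presets",
]

GWS_THRESHOLD = 5e-8
_GWS_Z = float(norm.isf(GWS_THRESHOLD / 2.0))

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Block spacing keeps distinct blocks far outside any plausible clump window.
_BLOCK_SPACING_BP = 5_000_000
_WITHIN_BLOCK_SPACING_BP = 50_000


@dataclass
class SimConfig:
    """Generative parameters for one synthetic exposure–outcome pair.

    Defaults emulate the largest exposure of the study design this package
    targets: a shingles-scale infection GWAS (16,711 cases / 118,152
    controls) with 15 instruments, against an AD case–control GWAS of
    21,982 / 41,944.
    """

    seed: int = 0
    n_exposure: int = 134_863
    n_outcome: int = 63_926
    case_fraction_x: float = 16_711 / 134_863
    case_fraction_y: float = 21_982 / 63_926
    j_instruments: int = 15
    n_null_snps: int = 60
    maf_range: tuple[float, float] = (0.05, 0.35)
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    ld_block_size: int = 3
    ld_within_r2: float = 0.25
    palindromic_frac: float = 0.2
    strand_flip_frac: float = 0.2
    f_range: tuple[float, float] = (60.0, 1000.0)
    label: str = "exposure"
    outcome_label: str = "outcome"
    snp_id_offset: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 0.5):
            raise ValidationError(f"maf_range must satisfy 0 < lo < hi < 0.5, got {self.maf_range}")
        for name in ("case_fraction_x", "case_fraction_y"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        for name in ("pleiotropy_frac", "outlier_frac", "palindromic_frac", "strand_flip_frac"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if min(self.n_exposure, self.n_outcome) < 100:
            raise ValidationError("sample sizes must be >= 100")
        if self.pleiotropy_sd < 0.0:
            raise ValidationError("pleiotropy_sd must be >= 0")
        if self.j_instruments < 1:
            raise ValidationError("j_instruments must be >= 1")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_r2 <= 1.0):
            raise ValidationError("ld_within_r2 must lie in [0, 1]")
        if not (0.0 < self.f_range[0] <= self.f_range[1]):
            raise ValidationError("f_range must be positive and ordered")


@dataclass
class OutcomeSpec:
    """One outcome study: sample size, case fraction, and per-exposure θ."""

    label: str
    n: int
    case_fraction: float
    theta: dict[str, float]


@dataclass
class StudyPreset:
    """A multi-exposure, multi-outcome study layout."""

    exposures: list[SimConfig]
    outcomes: list[OutcomeSpec]


@dataclass
class SimTruth:
    """Ground truth for one simulated exposure–outcome pair."""

    theta: float
    per_snp: pd.DataFrame  # snp_id, role, beta_x_true, alpha, outlier, swapped, strand_flipped


@dataclass
class StudyData:
    """All tables of a simulated multi-exposure study."""

    exposures: dict[str, SumStatsTable]
    outcomes: dict[str, SumStatsTable]
    ld: LdTable
    truth: dict[str, SimTruth]  # keyed "exposure_label::outcome_label"


def _se_binary(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * case_fraction * (1.0 - case_fraction))


def _draw_significant(rng, true_beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Observed betas, redrawn until genome-wide-significant (guaranteed)."""
    obs = rng.normal(true_beta, se)
    for _ in range(1000):
        weak = np.abs(obs / se) <= _GWS_Z
        if not weak.any():
            return obs
        obs[weak] = rng.normal(true_beta[weak], se[weak])
    raise ValidationError("could not draw genome-wide-significant instruments; f_range too low")


def _draw_alpha(cfg: SimConfig, rng, se_y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument direct effects α_j and the outlier mask."""
    J = cfg.j_instruments
    alpha = np.zeros(J)
    n_pleio = int(round(cfg.pleiotropy_frac * J))
    pleio_idx = rng.permutation(J)[:n_pleio]
    alpha[pleio_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)
    outlier = np.zeros(J, dtype=bool)
    n_out = int(round(cfg.outlier_frac * J))
    if n_out:
        out_idx = rng.permutation(J)[:n_out]
        outlier[out_idx] = True
        # Scale an existing direct effect, or plant one of outlier_scale
        # outcome-SEs when the background pleiotropy is zero.
        for i in out_idx:
            alpha[i] = alpha[i] * cfg.outlier_scale if alpha[i] != 0.0 \
                else cfg.outlier_scale * se_y[i]
    return alpha, outlier


@dataclass
class _Panel:
    """Internal: one exposure's SNP panel with truth arrays."""

    cfg: SimConfig
    records: list[GwasRecord]
    ld_entries: list[tuple[str, str, float]]
    maf: np.ndarray            # all panel SNPs
    beta_x_true: np.ndarray    # all panel SNPs
    roles: list[str]
    chroms: list[str]
    positions: list[int]
    alleles: list[tuple[str, str]]
    instrument_idx: np.ndarray
    alpha: np.ndarray          # per instrument
    outlier: np.ndarray        # per instrument


def _build_panel(cfg: SimConfig, rng) -> _Panel:
    cfg.validate()
    J = cfg.j_instruments
    n_sat_per_block = cfg.ld_block_size - 1
    n_panel = J * cfg.ld_block_size + cfg.n_null_snps

    maf = rng.uniform(*cfg.maf_range, size=n_panel)
    se_x = _se_binary(maf, cfg.n_exposure, cfg.case_fraction_x)

    beta_x_true = np.zeros(n_panel)
    roles: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    ld_entries: list[tuple[str, str, float]] = []
    instrument_idx = []

    def snp_id(i: int) -> str:
        return f"rs{cfg.snp_id_offset + i + 1}"

    idx = 0
    z_lead = np.sqrt(rng.uniform(*cfg.f_range, size=J))
    for j in range(J):
        block = j
        base = 1 + block * _BLOCK_SPACING_BP
        chrom = str(block % 22 + 1)
        lead = idx
        beta_x_true[lead] = z_lead[j] * se_x[lead]
        roles.append("instrument")
        chroms.append(chrom)
        positions.append(base)
        instrument_idx.append(lead)
        idx += 1
        block_members = [lead]
        for s in range(n_sat_per_block):
            # Satellite signal scales as sqrt(r2) of the lead's z-score, the
            # marginal association a correlated variant would show.
            beta_x_true[idx] = math.sqrt(cfg.ld_within_r2) * z_lead[j] * se_x[idx]
            roles.append("satellite")
            chroms.append(chrom)
            positions.append(base + (s + 1) * _WITHIN_BLOCK_SPACING_BP)
            block_members.append(idx)
            idx += 1
        for a in range(len(block_members)):
            for b in range(a + 1, len(block_members)):
                ld_entries.append(
                    (snp_id(block_members[a]), snp_id(block_members[b]), cfg.ld_within_r2)
                )

    for k in range(cfg.n_null_snps):
        block = J + k
        roles.append("null")
        chroms.append(str(block % 22 + 1))
        positions.append(1 + block * _BLOCK_SPACING_BP)
        idx += 1

    pal = rng.random(n_panel) < cfg.palindromic_frac
    alleles = []
    for i in range(n_panel):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])

    instrument_idx = np.array(instrument_idx, dtype=int)
    se_y_inst = _se_binary(maf[instrument_idx], cfg.n_outcome, cfg.case_fraction_y)
    alpha, outlier = _draw_alpha(cfg, rng, se_y_inst)

    beta_x_obs = rng.normal(beta_x_true, se_x)
    beta_x_obs[instrument_idx] = _draw_significant(
        rng, beta_x_true[instrument_idx], se_x[instrument_idx]
    )
    eaf_obs = np.clip(maf + rng.normal(0.0, 0.002, size=n_panel), 0.001, 0.499)

    records = [
        GwasRecord(
            snp_id=snp_id(i),
            chrom=chroms[i],
            pos=positions[i],
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(eaf_obs[i]),
            beta=float(beta_x_obs[i]),
            se=float(se_x[i]),
            pval=float(2.0 * norm.sf(abs(beta_x_obs[i] / se_x[i]))),
            n=cfg.n_exposure,
        )
        for i in range(n_panel)
    ]
    return _Panel(
        cfg=cfg, records=records, ld_entries=ld_entries, maf=maf,
        beta_x_true=beta_x_true, roles=roles, chroms=chroms,
        positions=positions, alleles=alleles,
        instrument_idx=instrument_idx, alpha=alpha, outlier=outlier,
    )


def _draw_outcome_for_panel(
    panel: _Panel, spec_n: int, spec_cf: float, theta: float, rng
) -> tuple[list[GwasRecord], SimTruth]:
    cfg = panel.cfg
    n_panel = len(panel.records)
    se_y = _se_binary(panel.maf, spec_n, spec_cf)

    beta_y_true = theta * panel.beta_x_true
    alpha_full = np.zeros(n_panel)
    alpha_full[panel.instrument_idx] = panel.alpha
    beta_y_true = beta_y_true + alpha_full
    beta_y_obs = rng.normal(beta_y_true, se_y)
    eaf_y = np.clip(panel.maf + rng.normal(0.0, 0.002, size=n_panel), 0.001, 0.499)

    swapped = rng.random(n_panel) < 0.5
    flipped = rng.random(n_panel) < cfg.strand_flip_frac

    records = []
    for i, exp_record in enumerate(panel.records):
        ea, oa = panel.alleles[i]
        beta = float(beta_y_obs[i])
        eaf = float(eaf_y[i])
        if swapped[i]:
            ea, oa = oa, ea
            beta = -beta
            eaf = 1.0 - eaf
        if flipped[i]:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        records.append(
            GwasRecord(
                snp_id=exp_record.snp_id,
                chrom=exp_record.chrom,
                pos=exp_record.pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=float(se_y[i]),
                pval=float(2.0 * norm.sf(abs(beta_y_obs[i] / se_y[i]))),
                n=spec_n,
            )
        )

    outlier_full = np.zeros(n_panel, dtype=bool)
    outlier_full[panel.instrument_idx] = panel.outlier
    per_snp = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in panel.records],
            "role": panel.roles,
            "beta_x_true": panel.beta_x_true,
            "alpha": alpha_full,
            "outlier": outlier_full,
            "swapped": swapped,
            "strand_flipped": flipped,
        }
    )
    return records, SimTruth(theta=theta, per_snp=per_snp)


def simulate_study(
    exposures: list[SimConfig],
    outcomes: list[OutcomeSpec],
    seed: int,
) -> StudyData:
    """Simulate a multi-exposure, multi-outcome two-sample study.

    Each exposure panel is drawn once and shared across outcomes (as in real
    designs, where one infection GWAS feeds both the discovery and the
    validation outcome); outcome associations are drawn per (exposure,
    outcome) with that outcome's sample size, case fraction, and true θ.
    SNP ids are disjoint across exposures.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(exposures))
    exposure_tables: dict[str, SumStatsTable] = {}
    outcome_records: dict[str, list[GwasRecord]] = {o.label: [] for o in outcomes}
    ld = LdTable()
    truth: dict[str, SimTruth] = {}

    for i, cfg in enumerate(exposures):
        cfg = replace(cfg, snp_id_offset=cfg.snp_id_offset or i * 1_000_000)
        rng = np.random.default_rng(children[i])
        panel = _build_panel(cfg, rng)
        exposure_tables[cfg.label] = SumStatsTable(
            study_label=cfg.label, trait_type="binary", records=panel.records
        )
        for snp_a, snp_b, r2 in panel.ld_entries:
            ld.add(snp_a, snp_b, r2)
        for spec in outcomes:
            theta = spec.theta.get(cfg.label, 0.0)
            records, pair_truth = _draw_outcome_for_panel(
                panel, spec.n, spec.case_fraction, theta, rng
            )
            outcome_records[spec.label].extend(records)
            truth[f"{cfg.label}::{spec.label}"] = pair_truth

    outcome_tables = {
        spec.label: SumStatsTable(
            study_label=spec.label, trait_type="binary",
            records=outcome_records[spec.label],
        )
        for spec in outcomes
    }
    return StudyData(
        exposures=exposure_tables, outcomes=outcome_tables, ld=ld, truth=truth
    )


def simulate_two_sample(
    cfg: SimConfig,
) -> tuple[SumStatsTable, SumStatsTable, LdTable, SimTruth]:
    """Simulate one exposure and one outcome table with LD and ground truth.

    Deterministic: identical (cfg, cfg.seed) gives byte-identical tables.
    """
    spec = OutcomeSpec(
        label=cfg.outcome_label, n=cfg.n_outcome,
        case_fraction=cfg.case_fraction_y, theta={cfg.label: cfg.theta},
    )
    study = simulate_study([cfg], [spec], cfg.seed)
    return (
        study.exposures[cfg.label],
        study.outcomes[cfg.outcome_label],
        study.ld,
        study.truth[f"{cfg.label}::{cfg.outcome_label}"],
    )


def simulate_harmonized(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[HarmonizedInstrument], dict]:
    """Fast path: draw one replicate of already-harmonized instrument effects.

    Skips table/allele plumbing (equivalent to the clean-scenario output of
    select → harmonize) and returns the per-instrument effect pairs plus the
    truth arrays.  Intended for calibration and power studies that need many
    thousands of replicates.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    J = cfg.j_instruments
    maf = rng.uniform(*cfg.maf_range, size=J)
    se_x = _se_binary(maf, cfg.n_exposure, cfg.case_fraction_x)
    se_y = _se_binary(maf, cfg.n_outcome, cfg.case_fraction_y)
    beta_x_true = np.sqrt(rng.uniform(*cfg.f_range, size=J)) * se_x
    alpha, outlier = _draw_alpha(cfg, rng, se_y)
    beta_x_obs = _draw_significant(rng, beta_x_true, se_x)
    beta_y_obs = rng.normal(cfg.theta * beta_x_true + alpha, se_y)
    hs = [
        HarmonizedInstrument(
            snp_id=f"rs{i + 1}",
            beta_x=float(beta_x_obs[i]), se_x=float(se_x[i]),
            beta_y=float(beta_y_obs[i]), se_y=float(se_y[i]),
            eaf_x=float(maf[i]), eaf_y=float(maf[i]),
            status="aligned",
        )
        for i in range(J)
    ]
    truth = {
        "theta": cfg.theta,
        "beta_x_true": beta_x_true,
        "alpha": alpha,
        "outlier": outlier,
        "se_x": se_x,
        "se_y": se_y,
    }
    return hs, truth


def scenario_presets() -> dict:
    """Named scenarios spanning the estimator guarantees.

    Single-pair presets are :class:`SimConfig`; ``paper_shaped`` is a
    :class:`StudyPreset` with four infection exposures (1, 2, 2, and 15
    instruments), a discovery AD outcome, and a family-history validation
    outcome at the corresponding cohort scales, with true effects equal to
    the log odds ratios such a study would report.
    """
    presets: dict = {
        "clean": SimConfig(theta=0.2, pleiotropy_sd=0.0),
        "balanced_pleiotropy": SimConfig(
            theta=0.2, j_instruments=50, pleiotropy_mean=0.0, pleiotropy_sd=0.02
        ),
        "directional_pleiotropy": SimConfig(
            theta=0.2, j_instruments=50, pleiotropy_mean=0.03, pleiotropy_sd=0.015
        ),
        "outliers": SimConfig(
            theta=0.2, j_instruments=15, outlier_frac=1.0 / 15.0, outlier_scale=10.0
        ),
    }
    exposures = [
        SimConfig(label="mononucleosis", j_instruments=1,
                  n_exposure=85_903, case_fraction_x=17_457 / 85_903,
                  n_null_snps=30),
        SimConfig(label="chickenpox", j_instruments=2,
                  n_exposure=123_751, case_fraction_x=107_769 / 123_751,
                  n_null_snps=30),
        SimConfig(label="cold_sores", j_instruments=2,
                  n_exposure=88_440, case_fraction_x=25_108 / 88_440,
                  n_null_snps=30),
        SimConfig(label="shingles", j_instruments=15,
                  n_exposure=134_863, case_fraction_x=16_711 / 134_863,
                  n_null_snps=30),
    ]
    presets["paper_shaped"] = StudyPreset(
        exposures=exposures,
        outcomes=[
            OutcomeSpec(
                label="alzheimers_disease", n=63_926,
                case_fraction=21_982 / 63_926,
                theta={
                    "mononucleosis": math.log(1.634),
                    "chickenpox": math.log(0.846),
                    "cold_sores": math.log(0.959),
                    "shingles": math.log(0.867),
                },
            ),
            OutcomeSpec(
                label="family_history_ad", n=314_278,
                case_fraction=42_034 / 314_278,
                theta={
                    "mononucleosis": math.log(1.392),
                    "chickenpox": math.log(1.147),
                    "cold_sores": math.log(0.966),
                    "shingles": math.log(1.047),
                },
            ),
        ],
    )
    return presets
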
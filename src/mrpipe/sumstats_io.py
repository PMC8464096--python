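"""Reading, validation, and writing of GWAS summary-statistics and LD tables.

The canonical internal schema follows the GWAS-SSF column convention
(``chromosome``, ``base_pair_location``, ``effect_allele``, ``other_allele``,
``effect_allele_frequency``, ``beta``, ``standard_error``, ``p_value``, ``n``)
plus a leading ``snp_id``.  A user-supplied *dialect* (a mapping from canonical
names to the file's actual headers) adapts other conventions on read.

Missing effect-allele frequency is tolerated (written as ``NA``); missing
beta/se/p is not.  Alleles are upper-cased on read and positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from ._errors import ConfigurationError, ValidationError

__all__ = [
    "GwasRecord",
    "SumStatsTable",
    "LdTable",
    "RejectedRow",
    "COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "read_ld_table",
]

#: Canonical column order for summary-statistics files.
COLUMNS = (
    "snp_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
)

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class GwasRecord:
    """One SNP's association statistics in one study.

    ``beta`` is the per-effect-allele effect; for binary traits it is on the
    log-odds scale.  ``eaf`` may be ``None`` (missing); ``se`` must be positive
    and ``pval`` must lie in (0, 1].
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: int

    def violations(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.effect_allele not in _VALID_ALLELES:
            problems.append(f"effect_allele: invalid allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            problems.append(f"other_allele: invalid allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            problems.append("other_allele: equals effect_allele")
        if self.pos < 1:
            problems.append("base_pair_location: must be >= 1")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append("effect_allele_frequency: outside [0, 1]")
        if not (self.se > 0.0) or not math.isfinite(self.se):
            problems.append("standard_error: must be finite and > 0")
        if not math.isfinite(self.beta):
            problems.append("beta: must be finite")
        if not (0.0 < self.pval <= 1.0):
            problems.append("p_value: outside (0, 1]")
        if self.n < 1:
            problems.append("n: must be >= 1")
        return problems

    @property
    def maf(self) -> Optional[float]:
        """Minor-allele frequency, or None when eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class RejectedRow:
    """A row that failed validation on read, with its 1-based line number."""

    line_number: int
    snp_id: str
    reasons: list[str]


@dataclass
class SumStatsTable:
    """An ordered collection of :class:`GwasRecord`, unique by ``snp_id``."""

    study_label: str
    trait_type: str = "binary"
    records: list[GwasRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValidationError(f"trait_type must be binary/continuous, got {self.trait_type!r}")
        self._index = {r.snp_id: r for r in self.records}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            dup = next(r.snp_id for r in self.records if r.snp_id in seen or seen.add(r.snp_id))
            raise ValidationError(f"duplicate snp_id in table: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GwasRecord]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> Optional[GwasRecord]:
        return self._index.get(snp_id)

    def subset(self, snp_ids, study_label: Optional[str] = None) -> "SumStatsTable":
        """New table with the given SNPs, preserving this table's order."""
        wanted = set(snp_ids)
        return SumStatsTable(
            study_label=study_label or self.study_label,
            trait_type=self.trait_type,
            records=[replace(r) for r in self.records if r.snp_id in wanted],
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chromosome": r.chrom,
                "base_pair_location": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "effect_allele_frequency": r.eaf,
                "beta": r.beta,
                "standard_error": r.se,
                "p_value": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _parse_float(text: str, column: str, line_number: int, allow_missing: bool = False):
    stripped = text.strip()
    if stripped in ("", "NA", "nan", "NaN", "."):
        if allow_missing:
            return None
        raise ValidationError(f"line {line_number}: missing value in column {column!r}")
    try:
        return float(stripped)
    except ValueError:
        raise ValidationError(
            f"line {line_number}: unparseable numeric {stripped!r} in column {column!r}"
        ) from None


def read_sumstats(
    path,
    dialect: Optional[dict] = None,
    study_label: Optional[str] = None,
    trait_type: str = "binary",
) -> SumStatsTable:
    """Read a tab-delimited summary-statistics file into a :class:`SumStatsTable`.

    ``dialect`` maps canonical column names (see :data:`COLUMNS`) to the
    file's actual headers; omitted entries default to the canonical name.
    Rows violating :class:`GwasRecord` invariants are collected on
    ``table.rejects`` with line numbers and field names, never silently
    dropped.  Missing mandatory columns raise :class:`ConfigurationError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping = {name: name for name in COLUMNS}
    if dialect:
        mapping.update(dialect)
    for canonical, actual in mapping.items():
        if actual not in frame.columns:
            raise ConfigurationError(
                f"{path}: required column {actual!r} (for {canonical!r}) missing from header"
            )

    records: list[GwasRecord] = []
    rejects: list[RejectedRow] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        line_number = i + 2  # header is line 1
        snp_id = str(row[mapping["snp_id"]]).strip()
        try:
            eaf = _parse_float(
                row[mapping["effect_allele_frequency"]],
                "effect_allele_frequency", line_number, allow_missing=True,
            )
            record = GwasRecord(
                snp_id=snp_id,
                chrom=str(row[mapping["chromosome"]]).strip(),
                pos=int(float(row[mapping["base_pair_location"]])),
                effect_allele=str(row[mapping["effect_allele"]]).strip().upper(),
                other_allele=str(row[mapping["other_allele"]]).strip().upper(),
                eaf=eaf,
                beta=_parse_float(row[mapping["beta"]], "beta", line_number),
                se=_parse_float(row[mapping["standard_error"]], "standard_error", line_number),
                pval=_parse_float(row[mapping["p_value"]], "p_value", line_number),
                n=int(float(row[mapping["n"]])),
            )
        except (ValidationError, ValueError) as exc:
            rejects.append(RejectedRow(line_number, snp_id, [str(exc)]))
            continue
        problems = record.violations()
        if snp_id in seen:
            problems.append("snp_id: duplicate within file")
        if problems:
            rejects.append(
                RejectedRow(line_number, snp_id, [f"line {line_number}: {p}" for p in problems])
            )
            continue
        seen.add(snp_id)
        records.append(record)

    return SumStatsTable(
        study_label=study_label or path.stem,
        trait_type=trait_type,
        records=records,
        rejects=rejects,
    )


def write_sumstats(table: SumStatsTable, path) -> Path:
    """Write a table in the canonical tab-delimited layout.

    Floats are serialized with ``repr`` (shortest round-trip representation),
    so write→read→write is byte-identical.  Missing eaf becomes ``NA``.
    """
    path = Path(path)
    lines = ["\t".join(COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                (
                    r.snp_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    "NA" if r.eaf is None else repr(r.eaf),
                    repr(r.beta),
                    repr(r.se),
                    repr(r.pval),
                    str(r.n),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


class LdTable:
    """Pairwise LD (r²) lookup with a symmetric contract.

    Lookups are orientation-independent, ``r2(a, a)`` is implicitly 1, and an
    unlisted pair returns ``None`` — "unknown", deliberately distinct from 0:
    the local table replaces a remote LD service, and absence of evidence must
    not be read as evidence of independence.  Clumping treats unknown pairs
    conservatively.
    """

    UNKNOWN = None

    def __init__(self, entries=()):
        self._r2: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, dict[str, float]] = {}
        for snp_a, snp_b, r2 in entries:
            self.add(snp_a, snp_b, float(r2))

    @staticmethod
    def _key(snp_a: str, snp_b: str) -> tuple[str, str]:
        return (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2 outside [0, 1] for pair ({snp_a}, {snp_b}): {r2}")
        if snp_a == snp_b:
            return  # r2(a, a) = 1 implicitly; nothing to store
        key = self._key(snp_a, snp_b)
        existing = self._r2.get(key)
        if existing is not None and existing != r2:
            raise ValidationError(
                f"conflicting duplicate LD entries for pair ({snp_a}, {snp_b}): "
                f"{existing} vs {r2}"
            )
        self._r2[key] = r2
        self._neighbors.setdefault(snp_a, {})[snp_b] = r2
        self._neighbors.setdefault(snp_b, {})[snp_a] = r2

    def lookup(self, snp_a: str, snp_b: str) -> Optional[float]:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(self._key(snp_a, snp_b), self.UNKNOWN)

    def neighbors(self, snp_id: str) -> dict[str, float]:
        """All SNPs with a stored r² against ``snp_id``."""
        return dict(self._neighbors.get(snp_id, {}))

    def __len__(self) -> int:
        return len(self._r2)

    def items(self):
        return self._r2.items()

    def write(self, path) -> Path:
        path = Path(path)
        lines = ["snp_a\tsnp_b\tr2"]
        for (snp_a, snp_b), r2 in sorted(self._r2.items()):
            lines.append(f"{snp_a}\t{snp_b}\t{repr(r2)}")
        path.write_text("\n".join(lines) + "\n")
        return path


def read_ld_table(path) -> LdTable:
    """Read a three-column tab-delimited LD table (snp_a, snp_b, r2)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"LD table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    for column in ("snp_a", "snp_b", "r2"):
        if column not in frame.columns:
            raise ConfigurationError(f"{path}: LD table missing column {column!r}")
    table = LdTable()
    for row in frame.itertuples(index=False):
        table.add(str(row.snp_a), str(row.snp_b), float(row.r2))
    return table
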
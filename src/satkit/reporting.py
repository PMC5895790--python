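"""Summary tables, fixture checks, and the replication-timing regression.

The package ships a transcription of the published catalogue of 26
*Vicia faba* satellite families (23 of them novel, named VfSat1..VfSat23,
plus the previously known FokI, TIII15 and pVf7): monomer length, genomic
abundance (% and Mbp per 1C, with 1C = 13.41 Gbp), AT content, the three
strand-asymmetry indices, and the CenH3 ChIP/input ratio with the
centromere assignment where the >10-fold call fired. The module recomputes
the derivable columns, audits printed-vs-recomputed inconsistencies
(reported, never silently corrected), and tests for association between
sequence features and replication-timing class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Callable, Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .util import round_half_away

__all__ = [
    "SatelliteRecord",
    "ReplicationRecord",
    "TIMING_LEVELS",
    "GENOME_SIZE_MBP",
    "mbp_per_1c",
    "read_fixture",
    "write_summary",
    "read_summary",
    "fixture_counts",
    "audit_mbp",
    "replication_regression",
]

#: haploid genome size of V. faba in Mbp (1C = 13.41 Gbp)
GENOME_SIZE_MBP = 13410.0

TIMING_LEVELS = ("mid", "late", "latest")

_COLUMNS = [
    "satellite",
    "monomer_bp",
    "monomer_bp_variant",
    "monomer_approx",
    "pct_genome",
    "mbp_1c",
    "pct_at",
    "max_at",
    "max_cg",
    "max_pupy",
    "chip_input_ratio",
    "centromere",
    "notes",
]


@dataclass
class SatelliteRecord:
    """One summary row for a satellite family."""

    name: str
    monomer_bp: int
    pct_genome: float
    mbp_1c: float
    pct_at: float
    max_at: float
    max_cg: float
    max_pupy: float
    chip_input_ratio: float
    centromere: str | None = None
    #: second monomer length where the family has a length variant
    monomer_bp_variant: int | None = None
    #: True where the printed monomer length was approximate ("~")
    monomer_approx: bool = False
    notes: str = ""


@dataclass(frozen=True)
class ReplicationRecord:
    family: str
    timing_class: str  # one of TIMING_LEVELS

    def __post_init__(self) -> None:
        if self.timing_class not in TIMING_LEVELS:
            raise ValueError(
                f"timing_class must be one of {TIMING_LEVELS}, got {self.timing_class!r}"
            )


def mbp_per_1c(pct: float, genome_mbp: float = GENOME_SIZE_MBP) -> float:
    """Convert a genomic percentage to Mbp per 1C, rounded half-away-from-zero
    to one decimal (the convention of the printed table)."""
    if pct < 0:
        raise ValueError("percentage must be >= 0")
    if genome_mbp <= 0:
        raise ValueError("genome size must be > 0")
    return round_half_away(pct / 100.0 * genome_mbp, 1)


# ---------------------------------------------------------------------------
# fixture / summary I/O


def _parse_row(parts: list[str], lineno: int) -> SatelliteRecord:
    parts = parts + [""] * (len(_COLUMNS) - len(parts))
    row = dict(zip(_COLUMNS, parts))
    try:
        return SatelliteRecord(
            name=row["satellite"],
            monomer_bp=int(row["monomer_bp"]),
            monomer_bp_variant=int(row["monomer_bp_variant"]) if row["monomer_bp_variant"] else None,
            monomer_approx=row["monomer_approx"] == "1",
            pct_genome=float(row["pct_genome"]),
            mbp_1c=float(row["mbp_1c"]),
            pct_at=float(row["pct_at"]),
            max_at=float(row["max_at"]),
            max_cg=float(row["max_cg"]),
            max_pupy=float(row["max_pupy"]),
            chip_input_ratio=float(row["chip_input_ratio"]),
            centromere=row["centromere"] or None,
            notes=row["notes"],
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed summary row at line {lineno}: {exc}") from exc


def _parse_tsv(text: str) -> list[SatelliteRecord]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[: len(_COLUMNS)] != _COLUMNS[: len(header)]:
        raise ValueError("unexpected summary header")
    return [_parse_row(ln.split("\t"), i + 2) for i, ln in enumerate(lines[1:])]


def read_fixture() -> list[SatelliteRecord]:
    """The packaged 26-family satellite catalogue."""
    text = (resources.files("satkit") / "data" / "vfaba_satellites.tsv").read_text()
    return _parse_tsv(text)


def read_summary(path: str) -> list[SatelliteRecord]:
    with open(path) as fh:
        return _parse_tsv(fh.read())


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def write_summary(records: Iterable[SatelliteRecord], path: str) -> None:
    """Write records as TSV with the fixed column order (read/write round-trips)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            row = [
                r.name, r.monomer_bp, r.monomer_bp_variant, r.monomer_approx,
                r.pct_genome, r.mbp_1c, r.pct_at, r.max_at, r.max_cg,
                r.max_pupy, r.chip_input_ratio, r.centromere, r.notes,
            ]
            fh.write("\t".join(_fmt(v) for v in row).rstrip("\t") + "\n")


# ---------------------------------------------------------------------------
# fixture queries


_OPS: dict[str, Callable] = {
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
    "eq": lambda v, t: v == t,
    "between": lambda v, t: t[0] <= v <= t[1],  # inclusive bounds
    "startswith": lambda v, t: str(v).startswith(t),
}

_FIELD_ALIASES = {"name": "name", "satellite": "name"}


def fixture_counts(
    table: list[SatelliteRecord], field: str, op: str, value
) -> int:
    """Count records whose ``field`` satisfies ``op`` against ``value``."""
    if not table:
        raise ValueError("table is empty")
    field = _FIELD_ALIASES.get(field, field)
    valid = {f.name for f in dc_fields(SatelliteRecord)}
    if field not in valid:
        raise ValueError(f"unknown predicate field {field!r}")
    if op not in _OPS:
        raise ValueError(f"unknown operator {op!r}")
    test = _OPS[op]
    return sum(1 for r in table if test(getattr(r, field), value))


def audit_mbp(
    table: list[SatelliteRecord],
    genome_mbp: float = GENOME_SIZE_MBP,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Recompute Mbp/1C from the printed percentage and report every row
    whose printed value differs by more than half a rounding unit. The
    discrepancies are reported, never corrected (the printed Mbp column was
    evidently derived from unrounded percentages)."""
    rows = []
    for r in table:
        recomputed = mbp_per_1c(r.pct_genome, genome_mbp)
        if abs(recomputed - r.mbp_1c) > tolerance:
            rows.append(
                {"satellite": r.name, "printed_mbp": r.mbp_1c, "recomputed_mbp": recomputed}
            )
    return pd.DataFrame(rows, columns=["satellite", "printed_mbp", "recomputed_mbp"])


# ---------------------------------------------------------------------------
# replication-timing regression


def replication_regression(
    features: pd.DataFrame,
    classes: list[ReplicationRecord],
    adjust: bool = False,
) -> pd.DataFrame:
    """Single-feature linear regressions of replication timing on sequence
    features.

    Timing is encoded ordinally (mid=0, late=1, latest=2, preserving the
    S-phase order) and regressed on each feature column separately; the
    two-sided t test on the slope is reported per feature. No
    multiple-testing correction by default; ``adjust=True`` adds
    Benjamini-Hochberg q-values.
    """
    timing = {c.family: TIMING_LEVELS.index(c.timing_class) for c in classes}
    missing = set(features.index) - set(timing)
    if missing:
        raise ValueError(f"no timing class for families: {sorted(missing)}")
    y = np.array([timing[f] for f in features.index], dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 families")

    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {col!r} is constant; no slope estimable")
            rows.append({"feature": col, "slope": np.nan, "t": np.nan, "p": np.nan})
            continue
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append(
            {
                "feature": col,
                "slope": model.params[1],
                "t": model.tvalues[1],
                "p": model.pvalues[1],
            }
        )
    out = pd.DataFrame(rows)
    if adjust:
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["q"] = q
    return out
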
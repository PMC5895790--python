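"""Best-hit read assignment and the abundance / enrichment tables.

Each read is assigned to at most one repeat family -- the one with the
highest local-alignment score against any member sequence of the family on
either strand, provided the score reaches the acceptance threshold. Ties
resolve to the lexicographically smallest family name and are counted.

From per-pool assignment tables the module derives genomic abundance
(fraction of reads, converted to Mbp per 1C genome) and ChIP/input
enrichment records with the >10-fold call rule used for centromere
identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .alignment import AlignParams, SeededPoolAligner, local_align_score
from .io import ReadRecord
from .util import round_half_away

__all__ = [
    "ReferenceSet",
    "ReadAssignmentTable",
    "EnrichmentParams",
    "assign_read",
    "assign_pool",
    "abundance_table",
    "enrichment_table",
]

UNASSIGNED = "-"

_VALID = set("ACGTN")


@dataclass
class ReferenceSet:
    """Named repeat families, each with one or more consensus sequences."""

    families: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("reference set must be non-empty")
        for name, seqs in self.families.items():
            if not seqs:
                raise ValueError(f"family {name!r} has no sequences")
            for s in seqs:
                if not s or set(s) - _VALID:
                    raise ValueError(
                        f"family {name!r}: sequences must be non-empty uppercase A/C/G/T/N"
                    )

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceSet":
        from .io import read_fasta

        return cls({name: [seq] for name, seq in read_fasta(path).items()})

    @classmethod
    def from_monomers(
        cls, monomers: dict[str, str], read_length: int = 100
    ) -> "ReferenceSet":
        """Tandem-extend monomer consensus sequences so that a read sampled
        at any phase of an array aligns over its full length (the analog of
        mapping against contigs longer than the repeat unit)."""
        fams = {}
        for name, mono in monomers.items():
            n_copies = max(1, math.ceil((len(mono) + read_length - 1) / len(mono)))
            fams[name] = [mono * n_copies]
        return cls(fams)

    @property
    def names(self) -> list[str]:
        return sorted(self.families)


@dataclass
class ReadAssignmentTable:
    """Per-read best-hit families plus pool-level counters."""

    assignments: pd.DataFrame  # columns: read_id, family, score
    total: int
    n_ties: int = 0
    _counts: pd.Series | None = field(default=None, repr=False)

    @property
    def counts(self) -> pd.Series:
        if self._counts is None:
            assigned = self.assignments[self.assignments["family"] != UNASSIGNED]
            self._counts = assigned.groupby("family", sort=True).size()
        return self._counts

    @property
    def n_assigned(self) -> int:
        return int(self.counts.sum())

    def proportions(self, denominator: str = "assigned") -> pd.Series:
        """Per-family read proportions.

        denominator="assigned": among reads assigned to any family;
        denominator="total": among all reads in the pool.
        """
        if denominator == "assigned":
            denom = self.n_assigned
        elif denominator == "total":
            denom = self.total
        else:
            raise ValueError("denominator must be 'assigned' or 'total'")
        if denom == 0:
            raise ValueError("no reads to normalize over")
        return self.counts / denom

    def to_tsv(self, path: str) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ReadAssignmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "family": str})
        return cls(df, total=len(df))


def assign_read(
    read: str | ReadRecord,
    refs: ReferenceSet,
    params: AlignParams = AlignParams(),
) -> tuple[str | None, int]:
    """Exact single-read assignment (full dynamic programming, no seeding)."""
    seq = read.seq if isinstance(read, ReadRecord) else read
    best_family: str | None = None
    best_score = 0
    for family in refs.names:  # sorted => lexicographic tie-break for free
        fam_best = 0
        for member in refs.families[family]:
            for target in (member, revcomp(member)):
                fam_best = max(fam_best, local_align_score(seq, target, params))
        if fam_best > best_score:
            best_family, best_score = family, fam_best
    if best_score < params.min_score:
        return None, best_score
    return best_family, best_score


def assign_pool(
    reads: list[ReadRecord],
    refs: ReferenceSet,
    params: AlignParams = AlignParams(),
    engine: SeededPoolAligner | None = None,
) -> ReadAssignmentTable:
    """Assign a pool of equal-length reads with the seeded batch engine.

    Output is sort-stable: the table is ordered by read id, so it is
    byte-identical regardless of input read order.
    """
    if engine is None:
        engine = SeededPoolAligner(refs.families, params)
    order = sorted(range(len(reads)), key=lambda i: reads[i].id)
    reads = [reads[i] for i in order]
    fam_idx, scores, ties = engine.best_scores([r.seq for r in reads])
    accepted = scores >= params.min_score
    fam_names = np.array(engine.families + [UNASSIGNED], dtype=object)
    families = fam_names[np.where(accepted & (fam_idx >= 0), fam_idx, len(engine.families))]
    df = pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "family": families,
            "score": scores,
        }
    )
    return ReadAssignmentTable(df, total=len(reads), n_ties=int(ties[accepted].sum()))


# ---------------------------------------------------------------------------
# derived tables


def abundance_table(
    table: ReadAssignmentTable,
    genome_size_mbp: float,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Genomic abundance per family: % of reads and physical size Mbp/1C.

    The percentage uses all reads in the pool as denominator (shotgun reads
    sample the genome uniformly, so read fraction estimates genome
    fraction); Mbp is rounded half-away-from-zero to one decimal for
    reporting, with the unrounded value kept alongside.
    """
    if table.total == 0:
        raise ValueError("assignment table has no reads")
    counts = table.counts
    if families is not None:
        counts = counts.reindex(sorted(families), fill_value=0)
    pct = counts / table.total * 100.0
    mbp_exact = pct / 100.0 * genome_size_mbp
    out = pd.DataFrame(
        {
            "family": counts.index,
            "read_count": counts.values,
            "pct_genome": pct.values,
            "mbp_1c": [round_half_away(v, 1) for v in mbp_exact.values],
            "mbp_1c_exact": mbp_exact.values,
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class EnrichmentParams:
    ratio_threshold: float = 10.0
    #: evaluation floor, in percent of the genome (input-derived).
    min_genomic_proportion: float = 0.002
    evaluate_top_n: int = 500
    #: proportion denominator: "assigned" or "total" (see Open design notes).
    denominator: str = "assigned"

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")


def enrichment_table(
    chip: ReadAssignmentTable,
    input_: ReadAssignmentTable,
    params: EnrichmentParams = EnrichmentParams(),
) -> pd.DataFrame:
    """Normalized ChIP/input ratios with the centromere call rule.

    A family is *called* when its ratio strictly exceeds the threshold and
    its genomic proportion (estimated from the input pool; from the ChIP
    pool when the input count is zero) meets the evaluation floor. Only the
    ``evaluate_top_n`` families by input count are evaluated.
    """
    if chip.total == 0 or input_.total == 0:
        raise ValueError("both pools must contain reads")
    families = sorted(set(chip.counts.index) | set(input_.counts.index))
    chip_n = chip.counts.reindex(families, fill_value=0)
    inp_n = input_.counts.reindex(families, fill_value=0)

    denom_chip = chip.n_assigned if params.denominator == "assigned" else chip.total
    denom_inp = input_.n_assigned if params.denominator == "assigned" else input_.total
    if denom_chip == 0 or denom_inp == 0:
        raise ValueError("no assigned reads to normalize over")
    chip_p = chip_n / denom_chip
    inp_p = inp_n / denom_inp

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(inp_p > 0, chip_p / inp_p, np.inf)
    ratio = np.where((chip_p == 0) & (inp_p == 0), np.nan, ratio)

    # genomic proportion floor (percent), input-derived; chip-derived as the
    # fallback for families absent from the input pool
    genomic_pct = np.where(
        inp_n > 0, inp_n / input_.total * 100.0, chip_n / chip.total * 100.0
    )

    rank = inp_n.rank(ascending=False, method="first")
    evaluated = (rank <= params.evaluate_top_n).to_numpy()
    called = (
        evaluated
        & (ratio > params.ratio_threshold)
        & (genomic_pct >= params.min_genomic_proportion)
    )

    return pd.DataFrame(
        {
            "family": families,
            "chip_count": chip_n.values,
            "input_count": inp_n.values,
            "chip_proportion": chip_p.values,
            "input_proportion": inp_p.values,
            "chip_input_ratio": ratio,
            "genomic_pct": genomic_pct,
            "evaluated": evaluated,
            "called": called,
        }
    )
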
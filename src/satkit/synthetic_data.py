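"""Synthetic satellite genomes, shotgun reads, and ChIP/input read pools.

Every downstream stage of the pipeline (QC, read assignment, abundance and
enrichment estimation) is exercised against data produced here, where the
planted truth — per-family genomic fraction, array coordinates, and ChIP
enrichment factor — is known exactly.

The generator emulates the regime of published plant satellite repeats:
AT-rich monomers (roughly 0.5-0.8 AT) of tens of bp up to ~2 kb, laid down
as uninterrupted tandem arrays of independently mutated monomer copies
(substitutions only), occupying genomic fractions from ~0.008 % up to a few
percent, sequenced as single-end reads of 101 nt, with an immunoprecipitated
pool whose family composition is re-weighted by a multiplicative enrichment
factor (1x for unenriched chromatin up to ~150x for centromere-bound
satellites).

Coordinates are 0-based, half-open throughout. A read belongs to the family
whose array contains its *start* position; this single rule keeps truth
accounting unambiguous for reads crossing array boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, revcomp_codes
from .io import PHRED_OFFSET, ReadRecord

__all__ = [
    "SatelliteFamilySpec",
    "GenomeSpec",
    "QualityModel",
    "ChipSimSpec",
    "FamilyTruth",
    "SyntheticTruth",
    "make_monomer",
    "mutate_copy",
    "build_genome",
    "simulate_reads",
    "simulate_chip",
]


# ---------------------------------------------------------------------------
# specs and truth containers


@dataclass(frozen=True)
class SatelliteFamilySpec:
    """One planted satellite family."""

    name: str
    monomer_length: int
    at_fraction: float = 0.65
    divergence: float = 0.05  # per-base substitution prob between array copies
    target_fraction: float = 0.01  # planted fraction of the genome

    def __post_init__(self) -> None:
        if self.monomer_length < 1:
            raise ValueError("monomer_length must be >= 1")
        for attr in ("at_fraction", "target_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must lie in [0, 0.3]")


@dataclass(frozen=True)
class GenomeSpec:
    genome_length: int
    families: tuple[SatelliteFamilySpec, ...]
    background_at: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("family names must be unique")
        if sum(f.target_fraction for f in self.families) > 1.0 + 1e-12:
            raise ValueError("family target fractions must sum to <= 1")


@dataclass(frozen=True)
class QualityModel:
    """Phred quality generator: constant Q, optionally with a low-quality
    3' tail on a fraction of reads (to exercise the QC filter)."""

    q: int = 30
    tail_q: int = 2
    tail_length: int = 0
    tail_fraction: float = 0.0

    def sample(self, n_reads: int, read_length: int, rng: np.random.Generator) -> np.ndarray:
        quals = np.full((n_reads, read_length), self.q, dtype=np.int16)
        if self.tail_fraction > 0.0 and self.tail_length > 0 and n_reads > 0:
            hit = rng.random(n_reads) < self.tail_fraction
            tail = min(self.tail_length, read_length)
            quals[hit, read_length - tail :] = self.tail_q
        return quals


@dataclass(frozen=True)
class ChipSimSpec:
    """Design of a ChIP/input sequencing pair with planted enrichment."""

    enrichment: dict[str, float]
    n_chip: int
    n_input: int
    read_length: int = 101
    error_rate: float = 0.01
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chip < 0 or self.n_input < 0:
            raise ValueError("read counts must be >= 0")
        for name, factor in self.enrichment.items():
            if factor < 0:
                raise ValueError(f"enrichment factor for {name!r} must be >= 0")


@dataclass
class FamilyTruth:
    fraction: float
    enrichment: float
    arrays: list[tuple[int, int]]  # 0-based half-open spans in the genome


@dataclass
class SyntheticTruth:
    """Planted ground truth: fractions, enrichment factors, array spans."""

    genome_length: int
    families: dict[str, FamilyTruth]
    monomers: dict[str, str]

    def recompute_fractions(self) -> dict[str, float]:
        return {
            name: sum(e - s for s, e in ft.arrays) / self.genome_length
            for name, ft in self.families.items()
        }

    def with_enrichment(self, enrichment: dict[str, float]) -> "SyntheticTruth":
        fams = {
            name: replace_enrichment(ft, enrichment.get(name, 1.0))
            for name, ft in self.families.items()
        }
        return SyntheticTruth(self.genome_length, fams, dict(self.monomers))

    def to_rows(self) -> list[dict]:
        return [
            {
                "family": name,
                "fraction": ft.fraction,
                "enrichment": ft.enrichment,
                "arrays": ";".join(f"{s}-{e}" for s, e in ft.arrays),
            }
            for name, ft in self.families.items()
        ]


def replace_enrichment(ft: FamilyTruth, factor: float) -> FamilyTruth:
    return FamilyTruth(ft.fraction, factor, list(ft.arrays))


# ---------------------------------------------------------------------------
# sequence generation


def _random_codes(n: int, at_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """iid encoded bases with P(A)=P(T)=at/2, P(C)=P(G)=(1-at)/2."""
    at = at_fraction
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def make_monomer(length: int, at_fraction: float, seed: int | np.random.Generator) -> str:
    """Generate a random monomer with the requested expected AT fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return decode(_random_codes(length, at_fraction, rng))


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability `rate` (never to itself)."""
    if rate <= 0.0:
        return codes.copy()
    out = codes.copy()
    mask = (rng.random(out.shape) < rate) & (out < 4)
    # shift by 1..3 within the 4-letter alphabet => always a different base
    out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out.astype(np.uint8)


def mutate_copy(monomer: str, divergence: float, rng: np.random.Generator) -> str:
    from ._seq import encode

    return decode(_mutate(encode(monomer), divergence, rng))


def build_genome(spec: GenomeSpec) -> tuple[dict[str, str], SyntheticTruth]:
    """Assemble a genome with one uninterrupted tandem array per family.

    Array length for a family is its target fraction rounded to a whole
    number of monomers (at least one when the target is positive). Arrays
    are separated by iid background sequence; the reported truth fractions
    are exact (array bases / genome length).
    """
    from ._seq import encode

    rng = np.random.default_rng(spec.seed)
    G = spec.genome_length

    monomers: dict[str, str] = {}
    array_codes: dict[str, np.ndarray] = {}
    for fam in spec.families:
        mono = make_monomer(fam.monomer_length, fam.at_fraction, rng)
        monomers[fam.name] = mono
        n_copies = int(round(fam.target_fraction * G / fam.monomer_length))
        if fam.target_fraction > 0 and n_copies == 0:
            n_copies = 1
        mono_codes = encode(mono)
        copies = [_mutate(mono_codes, fam.divergence, rng) for _ in range(n_copies)]
        array_codes[fam.name] = (
            np.concatenate(copies) if copies else np.empty(0, dtype=np.uint8)
        )

    total_array = sum(a.size for a in array_codes.values())
    if total_array > G:
        raise ValueError(
            f"planted arrays ({total_array} bp) do not fit in genome of {G} bp"
        )

    # distribute the background evenly into gaps around the arrays
    k = len(spec.families)
    gap_total = G - total_array
    gap_sizes = [gap_total // (k + 1)] * (k + 1)
    gap_sizes[-1] += gap_total - sum(gap_sizes)

    pieces: list[np.ndarray] = []
    truth_fams: dict[str, FamilyTruth] = {}
    pos = 0
    for i, fam in enumerate(spec.families):
        bg = _random_codes(gap_sizes[i], spec.background_at, rng)
        pieces.append(bg)
        pos += bg.size
        arr = array_codes[fam.name]
        pieces.append(arr)
        spans = [(pos, pos + arr.size)] if arr.size else []
        truth_fams[fam.name] = FamilyTruth(arr.size / G, 1.0, spans)
        pos += arr.size
    pieces.append(_random_codes(gap_sizes[-1], spec.background_at, rng))

    genome_codes = (
        np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    )
    assert genome_codes.size == G
    genome = {"genome": decode(genome_codes)}
    truth = SyntheticTruth(G, truth_fams, monomers)
    return genome, truth


# ---------------------------------------------------------------------------
# read simulation


def _genome_codes(genome: dict[str, str] | str) -> np.ndarray:
    from ._seq import encode

    seq = genome if isinstance(genome, str) else "".join(genome.values())
    return encode(seq)


def _reads_from_starts(
    codes: np.ndarray,
    starts: np.ndarray,
    read_length: int,
    error_rate: float,
    quality_model: QualityModel,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[ReadRecord]:
    n = starts.size
    if n == 0:
        return []
    window = starts[:, None] + np.arange(read_length)[None, :]
    reads = codes[window]
    strands = rng.integers(0, 2, size=n)  # 0 = forward, 1 = reverse
    rc = revcomp_codes(reads[strands == 1])
    reads[strands == 1] = rc
    reads = _mutate(reads, error_rate, rng)
    quals = quality_model.sample(n, read_length, rng) + PHRED_OFFSET
    qual_bytes = quals.astype(np.uint8)

    out: list[ReadRecord] = []
    strand_char = np.where(strands == 1, "-", "+")
    for i in range(n):
        out.append(
            ReadRecord(
                f"{id_prefix}{i}|pos={starts[i]}|strand={strand_char[i]}",
                decode(reads[i]),
                qual_bytes[i].tobytes().decode("ascii"),
            )
        )
    return out


def simulate_reads(
    genome: dict[str, str] | str,
    n_reads: int,
    read_length: int = 101,
    error_rate: float = 0.01,
    seed: int = 0,
    quality_model: QualityModel | None = None,
    id_prefix: str = "r",
) -> list[ReadRecord]:
    """Uniform single-end shotgun reads from both strands of the genome."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    codes = _genome_codes(genome)
    if read_length > codes.size:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, codes.size - read_length + 1, size=n_reads)
    qm = quality_model or QualityModel()
    return _reads_from_starts(codes, starts, read_length, error_rate, qm, rng, id_prefix)


def _start_pools(
    truth: SyntheticTruth, genome_length: int, read_length: int
) -> tuple[list[str], list[np.ndarray]]:
    """Valid start positions per family (start inside an array) and for the
    background (start outside every array)."""
    max_start = genome_length - read_length
    if max_start < 0:
        raise ValueError("read_length exceeds genome length")
    in_array = np.zeros(max_start + 1, dtype=bool)
    names: list[str] = []
    pools: list[np.ndarray] = []
    for name, ft in truth.families.items():
        mask = np.zeros(max_start + 1, dtype=bool)
        for s, e in ft.arrays:
            mask[s : min(e, max_start + 1)] = True
        names.append(name)
        pools.append(np.flatnonzero(mask))
        in_array |= mask
    names.append("__background__")
    pools.append(np.flatnonzero(~in_array))
    return names, pools


def simulate_chip(
    truth: SyntheticTruth,
    spec: ChipSimSpec,
    genome: dict[str, str] | str,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Simulate a ChIP/input pool pair.

    Input reads are sampled proportional to genomic fraction; ChIP reads
    proportional to fraction x enrichment factor, renormalized so pool
    proportions sum to one (the physical constraint of sequencing a fixed
    number of molecules).
    """
    unknown = set(spec.enrichment) - set(truth.families)
    if unknown:
        raise ValueError(f"enrichment keys not in truth: {sorted(unknown)}")
    for name, factor in spec.enrichment.items():
        if factor < 0:
            raise ValueError("enrichment factors must be >= 0")

    codes = _genome_codes(genome)
    names, pools = _start_pools(truth, codes.size, spec.read_length)
    weights = []
    for name, pool in zip(names, pools):
        frac = pool.size  # proportional to available starts ~ genomic fraction
        e = 1.0 if name == "__background__" else spec.enrichment.get(name, 1.0)
        weights.append((frac, frac * e))
    w_input = np.array([w[0] for w in weights], dtype=float)
    w_chip = np.array([w[1] for w in weights], dtype=float)

    rng = np.random.default_rng(spec.seed)

    def _sample_pool(n: int, w: np.ndarray, prefix: str) -> list[ReadRecord]:
        if n == 0:
            return []
        p = w / w.sum()
        labels = rng.choice(len(names), size=n, p=p)
        starts = np.empty(n, dtype=np.int64)
        for i, pool in enumerate(pools):
            idx = np.flatnonzero(labels == i)
            if idx.size:
                starts[idx] = rng.choice(pool, size=idx.size)
        return _reads_from_starts(
            codes, starts, spec.read_length, spec.error_rate,
            spec.quality_model, rng, prefix,
        )

    chip = _sample_pool(spec.n_chip, w_chip, "chip_")
    inp = _sample_pool(spec.n_input, w_input, "input_")
    return chip, inp
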
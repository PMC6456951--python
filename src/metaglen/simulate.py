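"""Synthetic metagenomic communities with known ground truth.

Generates communities of G species with low/medium/high-complexity (LC /
MC / HC) relative-abundance profiles, samples fixed-length shotgun reads
uniformly within genomes (genome chosen proportional to abundance times
genome length), and optionally applies per-base substitution errors.
Because every genome is known, the true distinct k-mer count, true total
genome length and the sample's *initial coverage* — the fraction of the
community's distinct k-mers present in the reads — are all computable
exactly, which is what makes the estimator testable end to end.

Complexity classes follow the usual qualitative definitions: LC has a
single dominant species, MC has two dominant species that jointly exceed
70% of the community, HC has no dominant species.  The concrete
constructions (0.6 dominant for LC; 0.45 + 0.30 for MC; symmetric
Dirichlet(5) for HC) are this package's fixed parameterisation of those
classes.

Genomes are i.i.d. uniform ACGT sequences in which a configurable
fraction is built by copying earlier segments of the same genome, so the
k-mer redundancy index of the set is controllably above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kri import GenomeSet, kri_of_genome_set
from .spectrum import SequenceSet, distinct_kmers

__all__ = [
    "Community",
    "ReadSample",
    "simulate_genomes",
    "assign_abundances",
    "make_community",
    "simulate_reads",
    "initial_coverage",
    "relative_error",
    "write_fasta",
    "write_fastq",
]

COMPLEXITY_CLASSES = ("LC", "MC", "HC")

_LC_DOMINANT = 0.6
_MC_DOMINANTS = (0.45, 0.30)
_GEOMETRIC_DECAY = 0.7
_HC_DIRICHLET_ALPHA = 5.0

_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _decode(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def simulate_genomes(
    n_species: int,
    genome_length: int,
    repeat_fraction: float = 0.1,
    seed: int = 0,
    min_segment: int = 200,
    max_segment: int = 2000,
) -> list[tuple[str, str]]:
    """Random genomes, one per species, with internal repeats.

    A fraction ``1 - repeat_fraction`` of each genome is uniform random
    ACGT; the remainder is filled by pasting copies of segments drawn
    from earlier parts of the same genome (segment lengths uniform in
    ``[min_segment, max_segment]``), producing tandem/dispersed repeats
    and a k-mer redundancy index strictly above 1.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0 <= repeat_fraction <= 0.9:
        raise ValueError("repeat_fraction must be in [0, 0.9]")
    if genome_length < 2:
        raise ValueError("genome_length too small")
    rng = np.random.default_rng(seed)
    genomes: list[tuple[str, str]] = []
    width = len(str(n_species))
    for s in range(n_species):
        core_len = max(1, round(genome_length * (1.0 - repeat_fraction)))
        parts = [rng.integers(0, 4, size=core_len, dtype=np.uint8)]
        total = core_len
        while total < genome_length:
            cur = np.concatenate(parts) if len(parts) > 1 else parts[0]
            seg_len = int(rng.integers(min_segment, max_segment + 1))
            seg_len = min(seg_len, genome_length - total, cur.size)
            start = int(rng.integers(0, cur.size - seg_len + 1))
            parts = [cur, cur[start : start + seg_len].copy()]
            total += seg_len
        codes = np.concatenate(parts)[:genome_length]
        genomes.append((f"sp{s + 1:0{width}d}", _decode(codes)))
    return genomes


def assign_abundances(n_species: int, complexity: str, seed: int = 0) -> np.ndarray:
    """Relative abundances for one community of the given complexity class.

    LC: one randomly chosen species gets 0.6; the rest share 0.4 with
    geometric decay.  MC: two random species get 0.45 and 0.30 (jointly
    0.75 > 0.7); the rest share 0.25 geometrically.  HC: symmetric
    Dirichlet(5), redrawn (bounded) until no species reaches 3/G.
    """
    if complexity not in COMPLEXITY_CLASSES:
        raise ValueError(f"unknown complexity {complexity!r}; expected one of {COMPLEXITY_CLASSES}")
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    if complexity == "HC":
        for _ in range(100):
            a = rng.dirichlet(np.full(n_species, _HC_DIRICHLET_ALPHA))
            if n_species < 3 or a.max() < 3.0 / n_species:
                return a
        raise RuntimeError("could not draw an HC profile without a dominant species")
    perm = rng.permutation(n_species)
    a = np.zeros(n_species)
    if complexity == "LC":
        n_dominant, mass = 1, _LC_DOMINANT
        a[perm[0]] = _LC_DOMINANT
    else:  # MC
        if n_species < 3:
            raise ValueError("MC communities need at least 3 species")
        n_dominant, mass = 2, sum(_MC_DOMINANTS)
        a[perm[0]], a[perm[1]] = _MC_DOMINANTS
    rest = perm[n_dominant:]
    if rest.size:
        tail = _GEOMETRIC_DECAY ** np.arange(rest.size)
        a[rest] = (1.0 - mass) * tail / tail.sum()
    return a


@dataclass
class Community:
    """A simulated metagenome: genomes, abundances and a complexity label."""

    genomes: list[tuple[str, str]]  # (species_id, sequence)
    abundances: np.ndarray
    complexity: str
    seed: int
    _genome_sets: dict[tuple[int, bool], GenomeSet] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        g = len(self.genomes)
        if a.shape != (g,):
            raise ValueError("one abundance per genome required")
        if np.any(a <= 0):
            raise ValueError("abundances must be strictly positive")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {a.sum()}, not 1")
        if self.complexity == "LC" and int(np.sum(a > 0.5)) != 1:
            raise ValueError("LC community must have exactly one species above 0.5")
        if self.complexity == "MC" and float(np.sort(a)[-2:].sum()) <= 0.7:
            raise ValueError("MC community must have two dominants jointly above 0.7")
        if self.complexity == "HC" and g >= 3 and float(a.max()) >= 3.0 / g:
            raise ValueError("HC community must have no dominant species")
        self.abundances = a

    @property
    def n_species(self) -> int:
        return len(self.genomes)

    def genome_set(self, k: int, canonical: bool = True) -> GenomeSet:
        """Pooled genome-set statistics (cached per (k, canonical))."""
        key = (k, canonical)
        if key not in self._genome_sets:
            self._genome_sets[key] = kri_of_genome_set(self.genomes, k=k, canonical=canonical)
        return self._genome_sets[key]

    def truth(self, k: int, canonical: bool = True) -> dict:
        """Ground-truth quantities the estimator is judged against."""
        gs = self.genome_set(k, canonical)
        return {
            "true_dkc": gs.dkc_union,
            "true_total_length": gs.total_genome_length,
            "true_kri": float(gs.kri),
            "n_species": self.n_species,
            "complexity": self.complexity,
        }


def make_community(
    n_species: int,
    genome_length: int,
    complexity: str,
    repeat_fraction: float = 0.1,
    seed: int = 0,
) -> Community:
    """Convenience constructor: genomes and abundances from one seed."""
    genomes = simulate_genomes(n_species, genome_length, repeat_fraction, seed=seed)
    abundances = assign_abundances(n_species, complexity, seed=seed + 1)
    return Community(genomes=genomes, abundances=abundances, complexity=complexity, seed=seed)


@dataclass
class ReadSample:
    """Fixed-length single-end reads drawn from a community."""

    reads: SequenceSet
    n_reads: int
    read_length: int
    error_rate: float
    seed: int
    community: Community | None = None


def simulate_reads(
    community: Community,
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSample:
    """Shotgun reads: genome ~ abundance x length, start uniform, substitutions i.i.d.

    Each base is substituted to one of the three other bases with
    probability ``error_rate``; no indels.  Deterministic given the seed.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    for sid, seq in community.genomes:
        if len(seq) < read_length:
            raise ValueError(f"genome {sid!r} is shorter than read_length = {read_length}")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(seq) for _, seq in community.genomes], dtype=float)
    p = community.abundances * lengths
    p = p / p.sum()
    records: list[tuple[str, str]] = []
    if n_reads > 0:
        per_genome = rng.multinomial(n_reads, p)
        idx = 0
        for (sid, seq), cnt in zip(community.genomes, per_genome):
            if cnt == 0:
                continue
            codes = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            starts = rng.integers(0, len(seq) - read_length + 1, size=cnt)
            rows = codes[starts[:, None] + np.arange(read_length)[None, :]]
            if error_rate > 0:
                mask = (rng.random(rows.shape) < error_rate) & (rows < 4)
                shifts = rng.integers(1, 4, size=rows.shape, dtype=np.uint8)
                rows = np.where(mask, (rows + shifts) % 4, rows)
            block = _ASCII[rows].tobytes()
            for row_i, start in enumerate(starts):
                idx += 1
                records.append(
                    (
                        f"r{idx}_{sid}_{int(start)}",
                        block[row_i * read_length : (row_i + 1) * read_length].decode("ascii"),
                    )
                )
    reads = SequenceSet(records=records) if records else SequenceSet(records=[], source=None)
    return ReadSample(
        reads=reads,
        n_reads=n_reads,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
        community=community,
    )


def initial_coverage(
    sample: ReadSample | SequenceSet,
    community: Community,
    k: int,
    canonical: bool = True,
) -> float:
    """Fraction of the community's distinct k-mers present in the sample."""
    seqs = sample.reads if isinstance(sample, ReadSample) else sample
    gs = community.genome_set(k, canonical)
    if len(seqs) == 0:
        return 0.0
    observed = distinct_kmers(seqs, k=k, canonical=canonical)
    shared = np.intersect1d(observed, gs.distinct, assume_unique=True)
    return float(shared.size) / float(gs.dkc_union)


def relative_error(estimate: float, truth: float) -> float:
    """Signed relative error (estimate - truth) / truth; truth must be > 0."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    return (estimate - truth) / truth


def write_fasta(genomes: list[tuple[str, str]] | SequenceSet, path, width: int = 80) -> None:
    """Plain FASTA writer (wrapped lines) for simulated genomes."""
    records = genomes.records if isinstance(genomes, SequenceSet) else genomes
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(sample: ReadSample, path) -> None:
    """Plain FASTQ writer; qualities are uniform 'I' placeholders."""
    with open(path, "w") as fh:
        for ident, seq in sample.reads:
            fh.write(f"@{ident}\n{seq}\n+\n{'I' * len(seq)}\n")
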
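"""k-mer counting and the k-mer frequency spectrum.

A DNA sequence of length L yields L - k + 1 overlapping k-mers.  Three
summary statistics of the resulting k-mer multiset drive everything in
this package:

* TKC (total k-mer count): the number of windows, ``sum_j j * n_j``;
  for a single sequence TKC = L - k + 1, so TKC is essentially the
  sequence length whenever L >> k.
* DKC (distinct k-mer count): the number of unique k-mers,
  ``sum_j n_j``.
* KRI (k-mer redundancy index): TKC / DKC >= 1, the mean multiplicity
  of a distinct k-mer; it measures repetitiveness and converts distinct
  k-mer counts back into sequence length.

The frequency spectrum ``n_j`` (the number of distinct k-mers seen
exactly j times) is the sufficient statistic consumed by the unseen
k-mer estimator in :mod:`metaglen.unseen`.

k-mers over {A, C, G, T} are packed into 2-bit codes (uint64, k <= 31);
windows containing any other symbol (N and friends) are skipped whole.
With ``canonical=True`` a k-mer and its reverse complement share one
key, the usual convention for reads of unknown strand.  For k > 31 a
plain string-keyed counter is used instead.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "KmerSpectrum",
    "count_kmers",
    "distinct_kmers",
    "spectrum_stats",
    "read_sequences",
    "read_histo",
    "write_histo",
    "MAX_PACKED_K",
]

MAX_PACKED_K = 31  # 2 bits/base in a uint64

# base -> 2-bit code; 4 flags N, 5 flags anything else
_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
for _b in "Nn":
    _CODE[ord(_b)] = 4

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class SequenceFormatError(ValueError):
    """Raised for malformed sequence input (bad symbols, empty records...)."""


class HistoFormatError(ValueError):
    """Raised for malformed k-mer histogram files."""


@dataclass
class SequenceSet:
    """A named collection of DNA sequences over {A, C, G, T, N}.

    Identifiers must be unique and sequences non-empty; symbol validity
    is checked lazily when the set is k-mer counted (so that huge inputs
    are scanned once, not twice).
    """

    records: list[tuple[str, str]]
    source: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ident, seq in self.records:
            if not seq:
                raise SequenceFormatError(f"record {ident!r} has an empty sequence")
            if ident in seen:
                raise SequenceFormatError(f"duplicate record identifier {ident!r}")
            seen.add(ident)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


@dataclass
class KmerSpectrum:
    """k-mer frequency spectrum: ``counts[j]`` distinct k-mers occur j times."""

    k: int
    canonical: bool
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        clean = {}
        for j, n in sorted(self.counts.items()):
            j, n = int(j), int(n)
            if j < 1:
                raise ValueError(f"frequency class {j} < 1")
            if n < 0:
                raise ValueError(f"negative count n_{j} = {n}")
            if n > 0:
                clean[j] = n
        self.counts = clean

    @property
    def dkc(self) -> int:
        """Distinct k-mer count, sum_j n_j."""
        return sum(self.counts.values())

    @property
    def tkc(self) -> int:
        """Total k-mer count, sum_j j * n_j."""
        return sum(j * n for j, n in self.counts.items())

    @property
    def kri(self) -> Fraction:
        """k-mer redundancy index TKC / DKC (exact rational, >= 1)."""
        dkc = self.dkc
        if dkc == 0:
            raise ValueError("empty spectrum has no KRI")
        return Fraction(self.tkc, dkc)

    @property
    def max_freq(self) -> int:
        return max(self.counts) if self.counts else 0

    def __bool__(self) -> bool:
        return bool(self.counts)


def spectrum_stats(spectrum: KmerSpectrum) -> tuple[int, int, Fraction]:
    """Return ``(TKC, DKC, KRI)`` of a spectrum; error on an empty one."""
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    return spectrum.tkc, spectrum.dkc, spectrum.kri


# ---------------------------------------------------------------------------
# packed-integer window codes


def _encode(ident: str, seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 5).any():
        pos = int(np.argmax(codes == 5))
        raise SequenceFormatError(
            f"record {ident!r} contains non-ACGTN symbol {seq[pos]!r} at position {pos}"
        )
    return codes


def _sorted_unique(a: np.ndarray, return_counts: bool = False):
    """Sort-based unique (predictable O(n log n); avoids hash-table paths)."""
    if a.size == 0:
        return (a, np.empty(0, dtype=np.int64)) if return_counts else a
    s = np.sort(a)
    boundary = np.empty(s.size, dtype=bool)
    boundary[0] = True
    np.not_equal(s[1:], s[:-1], out=boundary[1:])
    uniq = s[boundary]
    if not return_counts:
        return uniq
    idx = np.flatnonzero(boundary)
    counts = np.diff(np.append(idx, s.size))
    return uniq, counts


def _window_codes(codes: np.ndarray, k: int, canonical: bool) -> np.ndarray:
    """Packed codes of every valid k-window of one encoded sequence."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = codes >= 4
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad, dtype=np.int32)))
        valid = (cum[k:] - cum[:-k]) == 0
        codes = np.where(bad, 0, codes)
    else:
        valid = None
    del bad
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):  # fwd[i] = sum_j codes[i+j] * 4^(k-1-j)
        fwd <<= np.uint64(2)
        np.bitwise_or(fwd, codes[j : j + n], out=fwd)
    if canonical:
        comp = (np.uint8(3) - codes).astype(np.uint8)
        rev = np.zeros(n, dtype=np.uint64)
        buf = np.empty(n, dtype=np.uint64)  # reused scratch: no fresh big temporaries
        for j in range(k):
            np.copyto(buf, comp[j : j + n])
            buf <<= np.uint64(2 * j)
            rev |= buf
        np.minimum(fwd, rev, out=fwd)
    if valid is not None:
        fwd = fwd[valid]
    return fwd


def _all_window_codes(sequences: Iterable[tuple[str, str]], k: int, canonical: bool) -> np.ndarray:
    # Records are joined with an N separator and encoded in one pass; windows
    # spanning a junction contain the separator and are skipped like any
    # N-containing window.  On a bad symbol, rescan per record to name it.
    pairs = list(sequences)
    if not any(len(seq) >= k for _, seq in pairs):
        raise ValueError(f"k = {k} is larger than every input sequence")
    blob = "N".join(seq for _, seq in pairs)
    raw = np.frombuffer(blob.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 5).any():
        for ident, seq in pairs:
            _encode(ident, seq)  # raises, naming the offending record
        raise SequenceFormatError("non-ACGTN symbol in input")  # non-ascii replacement only
    return _window_codes(codes, k, canonical)


_RC = str.maketrans("ACGT", "TGCA")


def _string_kmers(sequences: Iterable[tuple[str, str]], k: int, canonical: bool) -> Counter:
    """Fallback counter for k > 31 (string keys; slow, small inputs only)."""
    counter: Counter = Counter()
    any_long_enough = False
    for ident, seq in sequences:
        _encode(ident, seq)  # symbol validation only
        s = seq.upper()
        if len(s) >= k:
            any_long_enough = True
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                rc = kmer.translate(_RC)[::-1]
                kmer = min(kmer, rc)
            counter[kmer] += 1
    if not any_long_enough:
        raise ValueError(f"k = {k} is larger than every input sequence")
    return counter


def count_kmers(sequences: SequenceSet, k: int, canonical: bool = True) -> KmerSpectrum:
    """Count all k-length windows of a sequence set and build the spectrum.

    Windows containing any N are skipped entirely.  With
    ``canonical=True`` each k-mer is keyed by the lexicographically
    smaller of itself and its reverse complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k <= MAX_PACKED_K:
        codes = _all_window_codes(sequences, k, canonical)
        if codes.size == 0:
            return KmerSpectrum(k=k, canonical=canonical, counts={})
        _, mult = _sorted_unique(codes, return_counts=True)
    else:
        counter = _string_kmers(sequences, k, canonical)
        if not counter:
            return KmerSpectrum(k=k, canonical=canonical, counts={})
        mult = np.fromiter(counter.values(), dtype=np.int64)
    freq, nj = _sorted_unique(np.asarray(mult), return_counts=True)
    counts = {int(j): int(n) for j, n in zip(freq, nj)}
    return KmerSpectrum(k=k, canonical=canonical, counts=counts)


def distinct_kmers(sequences: SequenceSet, k: int, canonical: bool = True) -> np.ndarray:
    """Sorted packed codes of the distinct k-mers in a sequence set (k <= 31)."""
    if not 1 <= k <= MAX_PACKED_K:
        raise ValueError(f"packed distinct k-mers require 1 <= k <= {MAX_PACKED_K}")
    codes = _all_window_codes(sequences, k, canonical)
    return _sorted_unique(codes)


# ---------------------------------------------------------------------------
# sequence file input


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    fh = open(path, "rb")
    if fh.read(2) == b"\x1f\x8b":
        fh.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    fh.seek(0)
    return io.TextIOWrapper(fh)


def read_sequences(path: str | Path) -> SequenceSet:
    """Read FASTA or FASTQ (plain or gzipped, sniffed) into a SequenceSet."""
    with _open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        else:
            raise SequenceFormatError(f"{path}: not FASTA or FASTQ (starts with {head!r})")
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]
    if not records:
        raise SequenceFormatError(f"{path}: no sequence records found")
    return SequenceSet(records=records, source=str(path))


# ---------------------------------------------------------------------------
# jellyfish-style two-column histogram files


def write_histo(spectrum: KmerSpectrum, path: str | Path) -> None:
    """Write ``frequency  count`` lines plus a header recording k/canonical."""
    with open(path, "w") as fh:
        fh.write(f"# metaglen histo k={spectrum.k} canonical={str(spectrum.canonical).lower()}\n")
        for j in sorted(spectrum.counts):
            fh.write(f"{j} {spectrum.counts[j]}\n")


def read_histo(
    path: str | Path, k: int | None = None, canonical: bool | None = None
) -> KmerSpectrum:
    """Parse a two-column k-mer frequency histogram (jellyfish ``histo`` style).

    The header comment written by :func:`write_histo` supplies k and the
    canonical flag; for a bare jellyfish file they must be passed in.
    """
    counts: dict[int, int] = {}
    last_j = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("k="):
                        k = int(tok[2:])
                    elif tok.startswith("canonical="):
                        canonical = tok[10:].lower() in ("true", "1", "yes")
                continue
            parts = line.split()
            if len(parts) != 2:
                raise HistoFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                j, n = int(parts[0]), int(parts[1])
            except ValueError:
                raise HistoFormatError(f"{path}:{lineno}: non-integer field in {line!r}") from None
            if j <= last_j:
                raise HistoFormatError(
                    f"{path}:{lineno}: frequency {j} not strictly increasing (previous {last_j})"
                )
            if n < 0:
                raise HistoFormatError(f"{path}:{lineno}: negative count {n}")
            counts[j] = n
            last_j = j
    if k is None:
        raise HistoFormatError(f"{path}: no k in header; pass k explicitly")
    if canonical is None:
        raise HistoFormatError(f"{path}: no canonical flag in header; pass it explicitly")
    return KmerSpectrum(k=k, canonical=canonical, counts=counts)
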
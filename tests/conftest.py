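"""Shared fixtures and the naive k-mer counting oracle."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from metaglen import SequenceSet, make_community

_RC = str.maketrans("ACGTN", "TGCAN")


def naive_kmer_counts(sequences, k: int, canonical: bool) -> Counter:
    """Substring-set enumeration oracle, independent of the packed counter."""
    counter: Counter = Counter()
    for _ident, seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                kmer = min(kmer, kmer.translate(_RC)[::-1])
            counter[kmer] += 1
    return counter


def naive_spectrum(sequences, k: int, canonical: bool) -> dict[int, int]:
    """Frequency spectrum n_j from the naive oracle."""
    mult = Counter(naive_kmer_counts(sequences, k, canonical).values())
    return dict(mult)


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_community():
    """A cheap 5-species HC community shared by simulator/pipeline tests."""
    return make_community(5, 20_000, "HC", repeat_fraction=0.1, seed=11)


@pytest.fixture
def toy_sequences():
    return SequenceSet(
        records=[("homopolymer", "AAAAAAAAAAAA"), ("periodic", "ACGTACGTACGT")]
    )
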
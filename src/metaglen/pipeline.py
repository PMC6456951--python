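"""Orchestration: spectrum -> unseen-DKC estimate -> KRI -> total length.

One run shares a single k and canonicalisation setting across every
stage; mixing conventions between the read spectrum and the genome set
would silently bias the KRI conversion, so mismatches abort before any
computation.  Partial runs (no genome set: estimate only) are allowed
and flagged with a warning in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .kri import kri_of_genome_set, total_length
from .simulate import initial_coverage, make_community, relative_error, simulate_reads
from .spectrum import KmerSpectrum, SequenceSet, count_kmers, read_histo, read_sequences
from .unseen import MomentProblemError, estimate_total_dkc

logger = logging.getLogger("metaglen")

__all__ = ["RunConfig", "Report", "run_pipeline", "run_validation_grid", "load_genome_set"]


@dataclass
class RunConfig:
    """All knobs for one pipeline run; echoed verbatim into the report."""

    reads: str | None = None
    histo: str | None = None
    genomes: list[str] = field(default_factory=list)
    species_map: str | None = None
    k: int = 20
    canonical: bool = True
    max_points: int = 10
    n_bootstrap: int = 100
    ci_level: float = 0.95
    seed: int = 1
    out: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Report:
    """Self-contained machine-readable result of one pipeline run."""

    config: dict
    spectrum: dict
    estimate: dict
    kri: dict | None = None
    total_length: dict | None = None
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def load_genome_set(
    paths: Sequence[str | Path],
    species_map: str | Path | None = None,
    k: int = 20,
    canonical: bool = True,
):
    """Read genome FASTA file(s) into a pooled, species-level GenomeSet.

    Without a mapping, each file is one species (all its records joined
    with an N separator so no window spans a contig junction).  With a
    two-column TSV ``record_id<TAB>species_id``, records from all files
    are grouped by species instead.
    """
    record_to_species: dict[str, str] | None = None
    if species_map is not None:
        record_to_species = {}
        with open(species_map) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2:
                    raise ValueError(f"{species_map}:{lineno}: expected two columns")
                record_to_species[parts[0]] = parts[1]
    grouped: dict[str, list[str]] = {}
    for path in paths:
        seqs = read_sequences(path)
        for ident, seq in seqs:
            if record_to_species is not None:
                try:
                    sid = record_to_species[ident]
                except KeyError:
                    raise ValueError(f"record {ident!r} missing from species map") from None
            else:
                sid = Path(str(path)).stem
            grouped.setdefault(sid, []).append(seq)
    genomes = [(sid, "N".join(seqs)) for sid, seqs in grouped.items()]
    return kri_of_genome_set(genomes, k=k, canonical=canonical)


def _spectrum_from_config(config: RunConfig) -> KmerSpectrum:
    if config.histo:
        spec = read_histo(config.histo, k=config.k, canonical=config.canonical)
        if spec.k != config.k:
            raise ValueError(
                f"histogram was counted at k = {spec.k} but the run is configured for k = {config.k}"
            )
        if spec.canonical != config.canonical:
            raise ValueError("histogram canonicalisation differs from the run configuration")
        return spec
    if config.reads:
        seqs = read_sequences(config.reads)
        return count_kmers(seqs, k=config.k, canonical=config.canonical)
    raise ValueError("either reads or a k-mer histogram must be provided")


def run_pipeline(config: RunConfig) -> Report:
    """Execute the full estimation workflow described by ``config``.

    Stages: build/ingest the k-mer spectrum; estimate total distinct
    k-mers with a bootstrap CI; if genomes are given, compute their
    pooled KRI and convert the DKC estimate into a total genome length.
    """
    warnings: list[str] = []
    logger.info("stage spectrum: k=%d canonical=%s", config.k, config.canonical)
    try:
        spec = _spectrum_from_config(config)
    except Exception as exc:
        raise type(exc)(f"[spectrum] {exc}") from exc
    spectrum_summary = {
        "k": spec.k,
        "canonical": spec.canonical,
        "tkc": spec.tkc,
        "dkc": spec.dkc,
        "max_freq": spec.max_freq,
    }

    logger.info("stage estimate: dkc_observed=%d", spec.dkc)
    try:
        est = estimate_total_dkc(
            spec,
            max_points=config.max_points,
            n_bootstrap=config.n_bootstrap,
            ci_level=config.ci_level,
            seed=config.seed,
        )
    except MomentProblemError as exc:
        raise MomentProblemError(f"[estimate] {exc}") from exc
    warnings.extend(est.warnings)
    estimate_summary = {
        "dkc_observed": est.dkc_observed,
        "uncaptured": est.uncaptured,
        "dkc_total": est.dkc_total,
        "ci_lower": est.ci_lower,
        "ci_upper": est.ci_upper,
        "ci_level": est.ci_level,
        "n_bootstrap": est.n_bootstrap,
        "n_points_used": est.n_points_used,
    }

    kri_summary = None
    length_summary = None
    if config.genomes:
        logger.info("stage kri: %d genome file(s)", len(config.genomes))
        try:
            gs = load_genome_set(
                config.genomes,
                species_map=config.species_map,
                k=config.k,
                canonical=config.canonical,
            )
        except Exception as exc:
            raise type(exc)(f"[kri] {exc}") from exc
        kri_summary = {
            "n_species": gs.n_species,
            "tkc_union": gs.tkc_union,
            "dkc_union": gs.dkc_union,
            "kri": float(gs.kri),
        }
        tl = total_length(est, float(gs.kri))
        length_summary = {
            "dkc_total": tl.dkc_total,
            "kri_estimate": tl.kri_estimate,
            "total_length": tl.total_length,
            "ci_lower": tl.ci_lower,
            "ci_upper": tl.ci_upper,
        }
    else:
        warnings.append("no genome set supplied; KRI and total length not computed")

    return Report(
        config=config.to_dict(),
        spectrum=spectrum_summary,
        estimate=estimate_summary,
        kri=kri_summary,
        total_length=length_summary,
        warnings=warnings,
    )


def run_validation_grid(
    species_counts: Sequence[int],
    complexities: Sequence[str],
    depths: Sequence[int],
    seeds: Sequence[int],
    genome_length: int = 100_000,
    read_length: int = 100,
    error_rate: float = 0.0,
    repeat_fraction: float = 0.1,
    k: int = 20,
    canonical: bool = True,
    max_points: int = 10,
    n_bootstrap: int = 0,
) -> pd.DataFrame:
    """Simulation-validation grid: one row per (G, complexity, depth, seed).

    Each cell simulates a community and a read sample, runs the DKC
    estimator, and records initial coverage, truth, estimate and
    relative error.  Cell failures are recorded in the ``error`` column
    and the grid continues.
    """
    rows = []
    for n_species in species_counts:
        for complexity in complexities:
            for seed in seeds:
                community = make_community(
                    n_species, genome_length, complexity, repeat_fraction, seed=seed
                )
                truth = community.truth(k, canonical)
                for n_reads in depths:
                    row = {
                        "n_species": n_species,
                        "complexity": complexity,
                        "n_reads": n_reads,
                        "seed": seed,
                        "true_dkc": truth["true_dkc"],
                        "true_total_length": truth["true_total_length"],
                        "initial_coverage": None,
                        "dkc_observed": None,
                        "dkc_total": None,
                        "ci_lower": None,
                        "ci_upper": None,
                        "relative_error": None,
                        "error": None,
                    }
                    try:
                        sample = simulate_reads(
                            community, n_reads, read_length, error_rate, seed=seed + 10_000
                        )
                        row["initial_coverage"] = initial_coverage(sample, community, k, canonical)
                        spec = count_kmers(sample.reads, k=k, canonical=canonical)
                        est = estimate_total_dkc(
                            spec, max_points=max_points, n_bootstrap=n_bootstrap, seed=seed
                        )
                        row["dkc_observed"] = est.dkc_observed
                        row["dkc_total"] = est.dkc_total
                        row["ci_lower"] = est.ci_lower
                        row["ci_upper"] = est.ci_upper
                        row["relative_error"] = relative_error(est.dkc_total, truth["true_dkc"])
                    except Exception as exc:  # cell failure must not kill the grid
                        row["error"] = str(exc)
                        logger.warning(
                            "grid cell failed (G=%d %s reads=%d seed=%d): %s",
                            n_species, complexity, n_reads, seed, exc,
                        )
                    rows.append(row)
    return pd.DataFrame(rows)
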
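"""Diploid single-end read simulator with known truth genotypes.

Reads are sampled from allele coding sequences only (hybridization capture
enriches the coding regions), with uniform start positions, optional PCR
duplicates, optional substitution errors and a configurable reverse-strand
fraction.  ``depth`` is the mean first-base coverage per allele copy: the
expected number of reads starting at each eligible CDS position, so the
expected read count per copy is depth x (len - read_len + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .reference import AlleleDatabase

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated library."""

    truth: Mapping[str, tuple[str, str]]  # gene -> unordered allele pair
    depth: float = 30.0
    read_len: int = 100
    dup_rate: float = 0.0
    error_rate: float = 0.0
    strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for f in ("dup_rate", "error_rate", "strand_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    seq: str
    source_allele: str
    start: int
    is_reverse: bool


@dataclass
class SimulatedReads:
    reads: list[SimRead]
    truth: dict[str, tuple[str, str]]
    spec: SimulationSpec = field(repr=False, default=None)

    def id_seq_pairs(self) -> list[tuple[str, str]]:
        return [(r.read_id, r.seq) for r in self.reads]

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")

    def write_manifest(self, truth_path: str | Path, sources_path: str | Path) -> None:
        with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\tallele1\tallele2\n")
            for gene in sorted(self.truth):
                a1, a2 = self.truth[gene]
                fh.write(f"{gene}\t{a1}\t{a2}\n")
        with open(sources_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("read_id\tsource_allele\tstart\tstrand\n")
            for r in self.reads:
                strand = "-" if r.is_reverse else "+"
                fh.write(f"{r.read_id}\t{r.source_allele}\t{r.start}\t{strand}\n")


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for p in hits:
        choices = bases[bases != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def simulate_reads(db: AlleleDatabase, spec: SimulationSpec) -> SimulatedReads:
    """Draw reads from every truth allele copy; deterministic for a seed.

    Duplicates are exact copies of already-emitted reads under fresh
    identifiers (they carry the same sequence, so deduplication collapses
    them while the multiplicity count is preserved).
    """
    for gene, pair in spec.truth.items():
        for name in pair:
            if name not in db:
                raise ValueError(f"truth allele {name!r} absent from database")
            if db.gene_of(name) != gene:
                raise ValueError(f"truth allele {name!r} is not a {gene} allele")
    min_len = min(len(db.get(n).cds) for pair in spec.truth.values() for n in pair)
    if spec.read_len > min_len:
        raise ValueError("read_len exceeds the shortest truth-allele CDS")

    rng = np.random.default_rng(spec.seed)
    reads: list[SimRead] = []
    counter = 0
    for gene in sorted(spec.truth):
        for copy_idx, allele in enumerate(spec.truth[gene]):
            cds = db.get(allele).cds
            n_start = len(cds) - spec.read_len + 1
            n_reads = int(rng.poisson(spec.depth * n_start))
            starts = rng.integers(0, n_start, size=n_reads)
            reverse = rng.random(n_reads) < spec.strand_fraction
            for s, rev in zip(starts, reverse):
                seq = cds[s : s + spec.read_len]
                if spec.error_rate > 0:
                    seq = _apply_errors(rng, seq, spec.error_rate)
                if rev:
                    seq = reverse_complement(seq)
                counter += 1
                reads.append(
                    SimRead(f"r{counter:07d}_{allele}_c{copy_idx}", seq, allele,
                            int(s), bool(rev))
                )
    if spec.dup_rate > 0:
        dup_mask = rng.random(len(reads)) < spec.dup_rate
        for i in np.flatnonzero(dup_mask):
            src = reads[i]
            reads.append(
                SimRead(src.read_id + "_dup", src.seq, src.source_allele,
                        src.start, src.is_reverse)
            )
    return SimulatedReads(reads=reads, truth=dict(spec.truth), spec=spec)
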
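"""Allele reference database: data model, FASTA/TSV readers and writers,
and a deterministic toy-database generator.

The mapping reference of the pipeline is the coding sequence (CDS) of each
allele — the concatenation of its exons — annotated with exon boundaries in
0-based half-open CDS coordinates.  Real databases (the IMGT/HLA nucleotide
FASTA dialect) and synthetic toy databases are handled by the same types.
"""

from __future__ import annotations

import csv
import logging
import re
import string
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger("hlacall")

DNA_ALPHABET = frozenset("ACGT")

_ALLELE_NAME_RE = re.compile(r"^(?P<gene>[A-Za-z0-9\-]+)\*(?P<fields>\d+[A-Z]?(?::\d+[A-Z]?)+)$")


class ReferenceError(ValueError):
    """Malformed allele database input."""


def parse_allele_name(name: str) -> tuple[str, tuple[str, ...]]:
    """Split ``GENE*f1:f2[:f3[:f4]]`` into gene symbol and resolution fields.

    An optional ``HLA-`` prefix is tolerated and stripped.
    """
    bare = name[4:] if name.startswith("HLA-") else name
    m = _ALLELE_NAME_RE.match(bare)
    if not m:
        raise ReferenceError(
            f"allele name {name!r} does not parse as GENE*field1:field2[...]"
        )
    return m.group("gene"), tuple(m.group("fields").split(":"))


@dataclass(frozen=True)
class AlleleRecord:
    """One allele: name, gene symbol, CDS and exon decomposition.

    ``exons`` are 0-based half-open intervals on the CDS; they must tile the
    CDS exactly (sorted, contiguous, union == [0, len(cds))).
    """

    name: str
    gene: str
    cds: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        gene, fields = parse_allele_name(self.name)
        if gene != self.gene:
            raise ReferenceError(
                f"allele {self.name!r}: gene field {self.gene!r} does not match name"
            )
        if len(fields) < 2:
            raise ReferenceError(f"allele {self.name!r}: fewer than two name fields")
        if not self.cds:
            raise ReferenceError(f"allele {self.name!r}: empty CDS")
        bad = set(self.cds) - DNA_ALPHABET
        if bad:
            # N is rejected on purpose: exact matching is undefined on N.
            raise ReferenceError(
                f"allele {self.name!r}: CDS contains non-ACGT characters {sorted(bad)}"
            )
        prev_end = 0
        for i, (start, end) in enumerate(self.exons):
            if start != prev_end:
                raise ReferenceError(
                    f"allele {self.name!r}: non-contiguous exons at index {i}"
                )
            if end <= start:
                raise ReferenceError(f"allele {self.name!r}: empty exon {i}")
            prev_end = end
        if prev_end != len(self.cds):
            raise ReferenceError(
                f"allele {self.name!r}: exons cover [0,{prev_end}) "
                f"but CDS has length {len(self.cds)}"
            )

    def exon_seq(self, index: int) -> str:
        start, end = self.exons[index]
        return self.cds[start:end]

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(end - start for start, end in self.exons)


@dataclass
class AlleleDatabase:
    """All alleles under consideration, grouped by gene.

    ``companion_genes`` are loci carried only because they are highly
    homologous to typed genes (the H and Y pseudogene companions of HLA-A):
    they take part in read-mapping, unique-read counting and the real-allele
    pool, but are never reported in the genotype.
    """

    alleles_by_gene: dict[str, list[AlleleRecord]]
    companion_genes: frozenset[str] = frozenset()
    _by_name: dict[str, AlleleRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {}
        for gene, recs in self.alleles_by_gene.items():
            for rec in recs:
                if rec.gene != gene:
                    raise ReferenceError(
                        f"allele {rec.name!r} filed under gene {gene!r}"
                    )
                if rec.name in self._by_name:
                    raise ReferenceError(f"duplicate allele name {rec.name!r}")
                self._by_name[rec.name] = rec

    @classmethod
    def from_records(
        cls,
        records: Iterable[AlleleRecord],
        companion_genes: Iterable[str] = (),
    ) -> "AlleleDatabase":
        by_gene: dict[str, list[AlleleRecord]] = {}
        for rec in records:
            by_gene.setdefault(rec.gene, []).append(rec)
        return cls(by_gene, frozenset(companion_genes))

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.alleles_by_gene)

    @property
    def reportable_genes(self) -> list[str]:
        return sorted(self.gene_set - self.companion_genes)

    def genes(self) -> list[str]:
        return sorted(self.alleles_by_gene)

    def alleles(self) -> Iterable[AlleleRecord]:
        for gene in self.genes():
            yield from self.alleles_by_gene[gene]

    def get(self, name: str) -> AlleleRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def gene_of(self, name: str) -> str:
        return self._by_name[name].gene

    def subset(self, names: Iterable[str]) -> "AlleleDatabase":
        """Database restricted to ``names``, preserving gene grouping/order."""
        keep = set(names)
        by_gene = {
            gene: [r for r in recs if r.name in keep]
            for gene, recs in self.alleles_by_gene.items()
        }
        by_gene = {g: rs for g, rs in by_gene.items() if rs}
        return AlleleDatabase(by_gene, self.companion_genes)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every numeric threshold of the calling pipeline, in one place.

    Defaults are the published operating points of the method:

    artificial_read_len
        length of the tiling k-mers generated from large exons (70 bp).
    large_exon_min
        an exon is "large" at >= 70 bp; large exons drive stage-1 coverage
        filtration and require >= 70 bp continuous alignment in local mapping.
    recip_exon_min
        exons >= 30 bp take part in local (per-exon) mapping; below 70 bp a
        read must contain the whole exon to count as mapped.
    identity_exon_min
        bait-QC considers exons longer than 23 bp, i.e. >= 24.
    window_len
        stage-2 scanning window over first-base positions (22 bp).
    full_read_len
        "continuously mapped" length for whole-read hits (100 bp single-end).
    asr_fold
        an allele with 15-fold fewer allele-specific reads than its partner
        is a potential false allele.
    pool_unique_min
        alleles with >= 6 unique mapped reads seed the real allele pool.
    max_unexplained_asr
        a pair still explains an ASR set with up to 8 unexplainable reads.
    null_support_min
        a null allele is reported with more than three (>= 4) deduplicated
        supporting reads.
    pass_value
        quality PASS iff highest score / number of evaluated pairs == 2.
    """

    artificial_read_len: int = 70
    large_exon_min: int = 70
    recip_exon_min: int = 30
    identity_exon_min: int = 24
    window_len: int = 22
    full_read_len: int = 100
    asr_fold: int = 15
    pool_unique_min: int = 6
    max_unexplained_asr: int = 8
    null_support_min: int = 4
    pass_value: int = 2
    # stage-1 rule: "coverage" requires the union of matched 70-mer spans to
    # cover every large-exon base; "gaps" is the literal adjacent-distance
    # (> 70 bp) formulation, which does not constrain the exon ends.
    stage1_rule: str = "coverage"
    max_pool_passes: int = 5
    # 1-based exon indices of the core exons used by the first-base
    # coverage metric (class-I antigen-recognition exons 2,3,4).
    core_exons: tuple[int, ...] = (2, 3, 4)
    # loci never reported in the genotype (pseudogene companions).
    companion_genes: tuple[str, ...] = ("H", "Y")
    # reported gene -> companion loci used for cross-paralog correction.
    paralog_companions: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"A": ("H", "Y"), "C": ("B",)}
    )
    # bait-QC: minimum contiguous complementary stretch supporting capture.
    min_complementary: int = 20

    def __post_init__(self) -> None:
        for f in (
            "artificial_read_len", "large_exon_min", "recip_exon_min",
            "identity_exon_min", "window_len", "full_read_len", "asr_fold",
            "pool_unique_min", "null_support_min", "pass_value",
            "max_pool_passes", "min_complementary",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"config: {f} must be positive")
        if self.max_unexplained_asr < 0:
            raise ValueError("config: max_unexplained_asr must be >= 0")
        if self.artificial_read_len > self.full_read_len:
            raise ValueError("config: artificial_read_len must be <= full_read_len")
        if self.window_len >= self.full_read_len:
            raise ValueError("config: window_len must be < full_read_len")
        if self.stage1_rule not in ("coverage", "gaps"):
            raise ValueError("config: stage1_rule must be 'coverage' or 'gaps'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        if "core_exons" in data:
            data["core_exons"] = tuple(data["core_exons"])
        if "companion_genes" in data:
            data["companion_genes"] = tuple(data["companion_genes"])
        if "paralog_companions" in data:
            data["paralog_companions"] = {
                k: tuple(v) for k, v in data["paralog_companions"].items()
            }
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, Mapping):
                v = {k: list(vv) for k, vv in v.items()}
            out[f.name] = v
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _allele_name_from_header(description: str) -> str:
    """Pick the allele-name token from a FASTA header.

    Accepts both the IMGT nucleotide dialect ``HLA:HLA00001 A*01:01:01:01
    1098 bp`` and bare ``>A*01:01:01`` headers: the name is the first token
    containing ``*``, else the first token.
    """
    tokens = description.split()
    for tok in tokens:
        if "*" in tok:
            return tok
    return tokens[0]


def read_exon_table(path: str | Path) -> dict[str, list[tuple[int, int, int]]]:
    """Read the exon-annotation TSV (allele, exon_index, start, end)."""
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "allele":
                continue  # header
            if len(row) != 4:
                raise ReferenceError(f"exon table line {lineno}: expected 4 columns")
            allele, idx, start, end = row
            rows.setdefault(allele, []).append((int(idx), int(start), int(end)))
    return rows


def read_allele_fasta(path: str | Path, exon_table: str | Path) -> AlleleDatabase:
    """Load an allele CDS FASTA plus its exon-annotation table.

    Alleles lacking exon annotations are rejected; sequences are uppercased;
    any character outside {A,C,G,T} (including N) is an error because the
    pipeline's matching contract is exact.
    """
    exons_by_allele = read_exon_table(exon_table)
    records: list[AlleleRecord] = []
    seen: set[str] = set()
    for seqrec in SeqIO.parse(str(path), "fasta"):
        name = _allele_name_from_header(seqrec.description)
        if name.startswith("HLA-"):
            name = name[4:]
        if name in seen:
            raise ReferenceError(f"duplicate allele name {name!r}")
        seen.add(name)
        if name not in exons_by_allele:
            raise ReferenceError(f"allele {name!r}: exon annotations required")
        gene, _ = parse_allele_name(name)
        rows = sorted(exons_by_allele[name])
        exons = tuple((start, end) for _, start, end in rows)
        records.append(
            AlleleRecord(name=name, gene=gene, cds=str(seqrec.seq).upper(), exons=exons)
        )
    return AlleleDatabase.from_records(records)


def write_allele_fasta(
    db: AlleleDatabase, fasta_path: str | Path, exon_path: str | Path
) -> None:
    """Write the database back out (bare headers); round-trips exactly."""
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in db.alleles():
            fh.write(f">{rec.name}\n{rec.cds}\n")
    with open(exon_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("allele\texon_index\tstart\tend\n")
        for rec in db.alleles():
            for i, (start, end) in enumerate(rec.exons):
                fh.write(f"{rec.name}\t{i}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Toy database generator
# ---------------------------------------------------------------------------

# Exon-length pattern loosely shaped like a class-I transcript: a leader
# exon, one sub-70 bp exon (exercises the full-exon local-mapping rule), and
# long antigen-binding exons; the pattern is extended with 200 bp exons and
# the remainder is absorbed by the last exon.
_EXON_PATTERN = (73, 50, 200, 276)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _tile_exons(cds_len: int, min_exon: int = 24) -> tuple[tuple[int, int], ...]:
    lengths: list[int] = []
    remaining = cds_len
    i = 0
    while remaining > 0:
        ln = _EXON_PATTERN[i] if i < len(_EXON_PATTERN) else 200
        ln = min(ln, remaining)
        lengths.append(ln)
        remaining -= ln
        i += 1
    if len(lengths) > 1 and lengths[-1] < min_exon:
        tail = lengths.pop()
        lengths[-1] += tail
    bounds = np.cumsum([0] + lengths)
    return tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _substitute(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != seq[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def make_toy_database(
    n_genes: int = 3,
    alleles_per_gene: int = 12,
    cds_len: int = 800,
    divergence: int = 4,
    paralog_pairs: Sequence[tuple[str, str]] = (("A", "H"),),
    seed: int = 0,
    paralog_identity: float = 0.95,
) -> AlleleDatabase:
    """Deterministic synthetic allele database emulating HLA homology.

    Each gene has a random ancestor CDS; every allele differs from it by
    exactly ``divergence`` substitutions at distinct positions (alleles are
    re-drawn on collision so all CDSs in a gene are distinct).  For each
    ``(primary, companion)`` paralog pair the companion gene's ancestor is a
    ``paralog_identity``-identical copy of the primary's, mimicking the
    HLA-A vs H/Y (and HLA-C vs B) homology.  Companion genes are flagged
    non-reportable.
    """
    if divergence < 1 and alleles_per_gene > 1:
        raise ValueError("divergence 0 with more than one allele per gene "
                         "would make alleles indistinguishable")
    if cds_len < 3 * 70:
        raise ValueError("cds_len must be at least 3x the large-exon minimum (210)")
    rng = np.random.default_rng(seed)
    companions = [c for _, c in paralog_pairs]
    primary = [g for g in string.ascii_uppercase if g not in companions][:n_genes]
    for p, _ in paralog_pairs:
        if p not in primary:
            raise ValueError(f"paralog pair references unknown primary gene {p!r}")
    exons = _tile_exons(cds_len)

    ancestors: dict[str, np.ndarray] = {g: _random_seq(rng, cds_len) for g in primary}
    for p, c in paralog_pairs:
        n_sub = int(round((1.0 - paralog_identity) * cds_len))
        pos = rng.choice(cds_len, size=n_sub, replace=False)
        ancestors[c] = _substitute(rng, ancestors[p], pos)

    records: list[AlleleRecord] = []
    for gene in primary + companions:
        anc = ancestors[gene]
        seen: set[bytes] = set()
        for i in range(alleles_per_gene):
            for _attempt in range(1000):
                pos = rng.choice(cds_len, size=divergence, replace=False)
                cds = _substitute(rng, anc, pos)
                key = cds.tobytes()
                if key not in seen:
                    seen.add(key)
                    break
            else:  # pragma: no cover - only reachable with absurd parameters
                raise ValueError("could not draw a distinct allele; "
                                 "increase divergence or cds_len")
            records.append(
                AlleleRecord(
                    name=f"{gene}*{i + 1:02d}:01",
                    gene=gene,
                    cds=cds.tobytes().decode("ascii"),
                    exons=exons,
                )
            )
    return AlleleDatabase.from_records(records, companion_genes=companions)
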
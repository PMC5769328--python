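"""Null-allele checking.

A null allele (no surface protein) is distinguishable from its expressed
parent only by short intron/exon-boundary signature sequences.  When a
reported genotype contains a trigger allele, the deduplicated reads are
scanned for the documented signatures; the null allele is flagged when
strictly more than three distinct (non-PCR-duplicated) reads support it.

The signature table is user-supplied configuration (TSV: trigger_allele,
null_name, signature); the package ships no real signatures, only the
schema and synthetic test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genotype import GenotypeReport
from .matching import ReadSet
from .reference import DNA_ALPHABET, PipelineConfig, parse_allele_name
from .simulate import reverse_complement


@dataclass(frozen=True)
class NullAlleleSignature:
    trigger_allele: str
    null_name: str
    signatures: tuple[str, ...]

    def __post_init__(self) -> None:
        parse_allele_name(self.trigger_allele)
        if not self.signatures:
            raise ValueError(f"{self.null_name}: at least one signature required")
        for sig in self.signatures:
            if not sig or set(sig) - DNA_ALPHABET:
                raise ValueError(
                    f"{self.null_name}: signature {sig!r} is not a non-empty "
                    "ACGT string"
                )


def load_signature_table(path: str | Path) -> list[NullAlleleSignature]:
    """Read the TSV table, grouping multiple signature rows per null allele."""
    grouped: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "trigger_allele":
                continue
            if len(parts) != 3:
                raise ValueError(f"signature table line {lineno}: expected 3 columns")
            key = (parts[0], parts[1])
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(parts[2].upper())
    return [
        NullAlleleSignature(trigger, null_name, tuple(grouped[(trigger, null_name)]))
        for trigger, null_name in order
    ]


def _strip_prefix(name: str) -> str:
    return name[4:] if name.startswith("HLA-") else name


def _matches_trigger(reported: str, trigger: str) -> bool:
    """True when the reported allele is the trigger at equal or finer
    resolution (field-boundary prefix match, HLA- prefix ignored)."""
    r, t = _strip_prefix(reported), _strip_prefix(trigger)
    return r == t or r.startswith(t + ":")


def count_signature_support(rs: ReadSet, signatures: Sequence[str]) -> int:
    """Distinct deduplicated reads containing any signature on either strand."""
    n = 0
    rcs = [reverse_complement(s) for s in signatures]
    for seq in rs.sequences():
        if any(s in seq for s in signatures) or any(s in seq for s in rcs):
            n += 1
    return n


def check_null_alleles(
    report: GenotypeReport,
    rs: ReadSet,
    table: Iterable[NullAlleleSignature],
    cfg: PipelineConfig,
) -> GenotypeReport:
    """Append null flags to gene calls whose alleles trigger a check."""
    for call in report.calls.values():
        for sig in table:
            if not any(_matches_trigger(a, sig.trigger_allele) for a in call.alleles):
                continue
            support = count_signature_support(rs, sig.signatures)
            if support >= cfg.null_support_min and sig.null_name not in call.null_flags:
                call.null_flags.append(sig.null_name)
    return report
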
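"""Reciprocal screening: allele-specific reads, false-allele exclusion,
real-allele-pool iteration, pair scoring and the PASS quality statistic.

The genotype of a gene is the unordered candidate pair that maximally
explains the allele-specific reads (ASRs) of every evaluated pair of that
gene, given the alleles believed present at the other loci (the "real
allele pool").  All unordered pairs including self-pairs are enumerated, so
homozygous genotypes are expressible; pairing is exhaustive rather than a
random sample, which is deterministic and strictly more informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .matching import ReadSet, hits_by_read, map_local_exons
from .reference import AlleleDatabase, PipelineConfig

logger = logging.getLogger("hlacall")

Pair = tuple[str, str]


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class AsrTable:
    """Per-read allele-mapping sets and derived allele-specific read sets.

    ``read_to_alleles`` maps each read id to every allele it attains a
    qualifying local-exon hit on, across all genes under consideration.
    ASR(a | b) — the reads specific to ``a`` within the pair (a, b) — is the
    set difference reads(a) - reads(b); a read mapping to both members is in
    neither set, so the two ASR sets of a pair are disjoint by construction.
    """

    read_to_alleles: dict[str, frozenset[str]]
    candidates_by_gene: dict[str, list[str]]
    gene_of: dict[str, str]
    reads_of_allele: dict[str, frozenset[str]] = field(init=False)
    unique_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        acc: dict[str, set[str]] = {a: set() for g in self.candidates_by_gene
                                    for a in self.candidates_by_gene[g]}
        uniq: dict[str, int] = {a: 0 for a in acc}
        for rid, alleles in self.read_to_alleles.items():
            for a in alleles:
                if a in acc:
                    acc[a].add(rid)
            if len(alleles) == 1:
                (a,) = alleles
                if a in uniq:
                    uniq[a] += 1
        self.reads_of_allele = {a: frozenset(s) for a, s in acc.items()}
        self.unique_counts = uniq

    def asr(self, a: str, b: str) -> frozenset[str]:
        """Reads mapping to ``a`` but not to ``b`` (ASR of a within (a,b))."""
        return self.reads_of_allele[a] - self.reads_of_allele[b]

    def restrict(self, keep_by_gene: Mapping[str, list[str]]) -> "AsrTable":
        return AsrTable(
            read_to_alleles=self.read_to_alleles,
            candidates_by_gene={g: list(v) for g, v in keep_by_gene.items()},
            gene_of=self.gene_of,
        )


def build_asr_table(
    db: AlleleDatabase,
    survivors: Iterable[str],
    rs: ReadSet,
    cfg: PipelineConfig,
) -> AsrTable:
    """Map the deduplicated reads locally against the surviving alleles.

    Genes left with zero survivors simply have an empty candidate list
    (reported untypeable downstream, never an exception).
    """
    sub = db.subset(survivors)
    hits = map_local_exons(rs, sub, cfg)
    read_to_alleles = hits_by_read(hits)
    candidates = {g: [] for g in db.genes()}
    for g in sub.genes():
        candidates[g] = [rec.name for rec in sub.alleles_by_gene[g]]
    gene_of = {rec.name: rec.gene for rec in sub.alleles()}
    return AsrTable(read_to_alleles, candidates, gene_of)


def seed_real_pool(asr: AsrTable, cfg: PipelineConfig) -> set[str]:
    """Alleles with >= pool_unique_min reads mapping to them alone."""
    return {a for a, n in asr.unique_counts.items() if n >= cfg.pool_unique_min}


def exclude_false_alleles(
    asr: AsrTable, cfg: PipelineConfig
) -> dict[str, list[str]]:
    """Drop potential false alleles by reciprocal ASR comparison.

    An allele is excluded iff some partner pairing gives it zero ASRs while
    the partner has some, or gives the partner >= asr_fold times as many.
    All exclusions are decided simultaneously from the pre-exclusion table
    (no cascade).  If a gene would lose every candidate, the allele(s) with
    the largest total ASR count are kept and a warning is logged.
    """
    out: dict[str, list[str]] = {}
    for gene, cands in asr.candidates_by_gene.items():
        excluded: set[str] = set()
        for i, a in enumerate(cands):
            for b in cands[i + 1 :]:
                ca, cb = len(asr.asr(a, b)), len(asr.asr(b, a))
                if ca == 0 and cb > 0:
                    excluded.add(a)
                elif cb == 0 and ca > 0:
                    excluded.add(b)
                else:
                    if ca > 0 and cb >= cfg.asr_fold * ca:
                        excluded.add(a)
                    if cb > 0 and ca >= cfg.asr_fold * cb:
                        excluded.add(b)
        kept = [a for a in cands if a not in excluded]
        if cands and not kept:
            totals = {
                a: sum(len(asr.asr(a, b)) for b in cands if b != a) for a in cands
            }
            best = max(totals.values())
            kept = [a for a in cands if totals[a] == best]
            logger.warning(
                "exclusion removed every %s candidate; keeping %s by total ASR",
                gene, kept,
            )
        out[gene] = kept
    return out


@dataclass
class GenePairScore:
    """Score of one candidate pair: one point per explained allele-instance."""

    gene: str
    pair: Pair
    score: int
    # (evaluated pair, member) -> count of its ASRs this pair cannot explain
    explained_detail: dict[tuple[Pair, str], int] = field(default_factory=dict)


def all_pairs(candidates: list[str]) -> list[Pair]:
    """All unordered pairs, self-pairs included, in deterministic order."""
    cands = sorted(candidates)
    return [
        _ordered(cands[i], cands[j])
        for i in range(len(cands))
        for j in range(i, len(cands))
    ]


def score_pairs(
    gene: str,
    candidates: list[str],
    pool: set[str],
    asr: AsrTable,
    cfg: PipelineConfig,
) -> list[GenePairScore]:
    """Score every candidate pair of ``gene`` against every allele-instance.

    For each evaluated pair Q and each member m of Q, the instance's ASR set
    is "explained" by pair P iff at most ``max_unexplained_asr`` of its reads
    fail to map to any allele of P or of the other genes' pool alleles; each
    explained instance earns P one point, so a pair explaining everything
    scores 2 x (number of evaluated pairs).
    """
    pairs = all_pairs(candidates)
    other_pool = frozenset(p for p in pool if asr.gene_of.get(p) != gene)
    # instance = (Q, member); precompute the mapping set of each ASR read
    instances: list[tuple[Pair, str, list[frozenset[str]]]] = []
    for q in pairs:
        x, y = q
        for member, partner in ((x, y), (y, x)):
            mapsets = [asr.read_to_alleles[r] for r in sorted(asr.asr(member, partner))]
            instances.append((q, member, mapsets))

    results: list[GenePairScore] = []
    for p in pairs:
        explain = other_pool | set(p)
        score = 0
        detail: dict[tuple[Pair, str], int] = {}
        for q, member, mapsets in instances:
            unexplained = sum(1 for ms in mapsets if ms.isdisjoint(explain))
            detail[(q, member)] = unexplained
            if unexplained <= cfg.max_unexplained_asr:
                score += 1
        results.append(GenePairScore(gene, p, score, detail))
    return results


def top_pairs(scores: list[GenePairScore]) -> list[Pair]:
    if not scores:
        return []
    best = max(s.score for s in scores)
    return [s.pair for s in scores if s.score == best]


def iterate_pool(
    asr: AsrTable,
    seed_pool: set[str],
    cfg: PipelineConfig,
    score_genes: list[str] | None = None,
) -> tuple[dict[str, list[GenePairScore]], dict[str, list[Pair]], bool]:
    """Re-score every gene until the top pairs stabilise.

    The pool is held fixed within a pass (seed pool plus all top-pair
    alleles from the previous pass), so results do not depend on the order
    genes are visited.  Returns the final score tables, the per-gene top
    pairs and a convergence flag (False if the cap of ``max_pool_passes``
    was hit while still changing).
    """
    if score_genes is None:
        score_genes = sorted(asr.candidates_by_gene)
    tops: dict[str, list[Pair]] = {g: [] for g in score_genes}
    scores: dict[str, list[GenePairScore]] = {g: [] for g in score_genes}
    converged = False
    for _pass in range(cfg.max_pool_passes):
        pool = set(seed_pool)
        for pairs in tops.values():
            for a, b in pairs:
                pool.update((a, b))
        new_tops: dict[str, list[Pair]] = {}
        for gene in score_genes:
            scores[gene] = score_pairs(
                gene, asr.candidates_by_gene.get(gene, []), pool, asr, cfg
            )
            new_tops[gene] = top_pairs(scores[gene])
        if new_tops == tops:
            converged = True
            break
        tops = new_tops
    if not converged:
        logger.warning("real-allele-pool iteration did not converge in %d passes",
                       cfg.max_pool_passes)
    return scores, tops, converged


def quality_check(
    scores: list[GenePairScore], cfg: PipelineConfig
) -> tuple[float, bool]:
    """Highest score divided by the number of evaluated pairs; PASS iff == 2.

    Exact integer arithmetic: PASS requires score == pass_value x n_pairs,
    i.e. the top pair explains both allele-instances of every pair.
    """
    if not scores:
        return 0.0, False
    n_pairs = len(scores)
    best = max(s.score for s in scores)
    value = best / n_pairs
    return value, best == cfg.pass_value * n_pairs


@dataclass
class GeneCall:
    """Final call for one gene."""

    gene: str
    alleles: tuple[str, ...]  # pair, or single allele after paralog correction
    ambiguity: list[Pair]  # all tied top-score pairs
    quality_value: float
    quality: str  # "PASS" | "NOT_PASS"
    null_flags: list[str] = field(default_factory=list)
    top_score: int = 0
    n_pairs: int = 0


@dataclass
class GenotypeReport:
    calls: dict[str, GeneCall]
    config: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "calls": {
                g: {
                    "alleles": list(c.alleles),
                    "ambiguity": [list(p) for p in c.ambiguity],
                    "quality_value": c.quality_value,
                    "quality": c.quality,
                    "null_flags": list(c.null_flags),
                    "top_score": c.top_score,
                    "n_pairs": c.n_pairs,
                }
                for g, c in sorted(self.calls.items())
            },
        }


def paralog_correction(
    call: GeneCall,
    asr: AsrTable,
    cfg: PipelineConfig,
) -> GeneCall:
    """Cross-paralog correction for highly homologous companion loci.

    For a reported pair of a gene with companion loci (HLA-A vs H/Y, HLA-C
    vs B): if exactly one member's entire ASR set (within the pair) maps
    into the remaining companion alleles, that member is an artifact of
    cross-locus capture and is removed, leaving a single reported allele.
    If both or neither member is fully explained, the pair stands.
    """
    companions = cfg.paralog_companions.get(call.gene)
    if not companions:
        return call
    companion_alleles = frozenset(
        a for g in companions for a in asr.candidates_by_gene.get(g, [])
    )
    if not companion_alleles:
        return call
    new_alleles: tuple[str, ...] = call.alleles
    if len(call.alleles) == 2:
        m1, m2 = call.alleles
        def fully_explained(member: str, partner: str) -> bool:
            return all(
                not asr.read_to_alleles[r].isdisjoint(companion_alleles)
                for r in asr.asr(member, partner)
            )
        e1 = fully_explained(m1, m2)
        e2 = fully_explained(m2, m1)
        if e1 != e2:
            removed, kept = (m1, m2) if e1 else (m2, m1)
            logger.info(
                "paralog correction: %s %s fully explained by %s; reporting %s",
                call.gene, removed, "/".join(companions), kept,
            )
            new_alleles = (kept,)
    return GeneCall(
        gene=call.gene,
        alleles=new_alleles,
        ambiguity=call.ambiguity,
        quality_value=call.quality_value,
        quality=call.quality,
        null_flags=call.null_flags,
        top_score=call.top_score,
        n_pairs=call.n_pairs,
    )
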
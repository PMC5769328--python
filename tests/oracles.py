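"""Independent brute-force oracles used to verify the mapping engine,
the pair scorer and the bait-QC analytics.

Everything here scans offsets exhaustively (or runs a full DP) and shares
no code with the implementations under test.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def end_to_end_hits(reads, db, min_contig):
    """Every (read_id, allele, start, len, is_reverse) whole-read match,
    found by comparing the read against every offset of every allele."""
    hits = set()
    alleles = [(rec.name, rec.cds) for rec in db.alleles()]
    for read_id, seq in reads:
        if len(seq) < min_contig:
            continue
        for is_rev, s in ((False, seq), (True, rc(seq))):
            for name, cds in alleles:
                for pos in range(len(cds) - len(s) + 1):
                    if cds[pos : pos + len(s)] == s:
                        hits.add((read_id, name, pos, len(s), is_rev))
    return hits


def maximal_common_runs(a: str, b: str):
    """All maximal exact shared contiguous substrings of a and b as
    (a_start, b_start, length), by extending from every start pair."""
    runs = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not a run start
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            runs.add((i, j, k))
    return runs


def local_exon_hits(reads, db, cfg):
    """Per-exon local hits under the published length rules, brute force."""
    hits = set()
    for read_id, seq in reads:
        for is_rev, s in ((False, seq), (True, rc(seq))):
            for rec in db.alleles():
                for e_idx, (e_start, e_end) in enumerate(rec.exons):
                    e_len = e_end - e_start
                    exon = rec.cds[e_start:e_end]
                    if e_len >= cfg.large_exon_min:
                        for e_pos, _r_pos, run_len in maximal_common_runs(exon, s):
                            if run_len >= cfg.large_exon_min:
                                hits.add((read_id, rec.name,
                                          e_start + e_pos, run_len, is_rev, e_idx))
                    elif e_len >= cfg.recip_exon_min:
                        if exon in s:
                            hits.add((read_id, rec.name, e_start, e_len,
                                      is_rev, e_idx))
    return hits


def artificial_matches(artificial, reads):
    """(allele, exon) -> sorted offsets whose k-mer occurs in any read."""
    out = {}
    for allele, e_idx, off, kmer in artificial:
        out.setdefault((allele, e_idx), [])
        if any(kmer in seq or rc(kmer) in seq for _, seq in reads):
            out[(allele, e_idx)].append(off)
    return {k: sorted(v) for k, v in out.items()}


def max_matches_alignment(a: str, b: str) -> int:
    """Maximum number of matched bases over all global alignments with unit
    match score and zero mismatch/gap score (= LCS length), full DP."""
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[len(b)]


def covered_positions(query: str, bait: str, min_len: int) -> set[int]:
    """Query positions inside some exact shared run >= min_len, brute force."""
    covered = set()
    for q_start, _b_start, length in maximal_common_runs(query, bait):
        if length >= min_len:
            covered.update(range(q_start, q_start + length))
    return covered


def score_pairs_bruteforce(gene, candidates, pool, read_to_alleles,
                           reads_of_allele, gene_of, max_unexplained):
    """Pair scores recomputed directly from the raw read->allele map sets."""
    cands = sorted(candidates)
    pairs = [(cands[i], cands[j]) for i in range(len(cands))
             for j in range(i, len(cands))]
    other_pool = {p for p in pool if gene_of.get(p) != gene}
    scores = {}
    for p in pairs:
        explain = other_pool | set(p)
        score = 0
        for q in pairs:
            for member, partner in (q, q[::-1]):
                asr = reads_of_allele[member] - reads_of_allele[partner]
                unexplained = sum(
                    1 for r in asr if not (read_to_alleles[r] & explain)
                )
                if unexplained <= max_unexplained:
                    score += 1
        scores[p] = score
    return scores
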
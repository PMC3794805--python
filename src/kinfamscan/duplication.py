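"""Paralog-pair calling by coverage/identity thresholds.

All unordered gene pairs are evaluated with global nucleotide alignment
(brute force — the family scale makes heuristics unnecessary). A pair is
reported iff the aligned region covers more than 80% of the longer gene
AND its identity exceeds 80% (both strict inequalities; a pair at exactly
0.8 is excluded). Reported pairs on one chromosome within the linkage
window are "tandem"; tightly linked pairs are merged so a tandem cluster
counts as a single duplication event.

Two prefilters are used, both exact (a skipped pair provably cannot
qualify): (1) the aligned (both-residue) length and the match count
cannot exceed the shorter gene, so a pair whose length ratio is <= the
thresholds can never pass; (2) an identity > t alignment with m matches
has fewer than (1/t - 1) m penalized columns, each costing at most
max(|mismatch|, gap_open + gap_extend), so its score exceeds a bound
linear in the longer length — pairs whose optimal score (computed
without traceback) is at or below that bound are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import (NUCLEOTIDE_SCORING, PROTEIN_SCORING, ScoringScheme,
                    global_align, global_score)
from .genestruct import ExonChain
from .seqio import SeqEntry, logger


@dataclass(frozen=True)
class DuplicationPair:
    gene_a: str
    gene_b: str
    coverage_longer: float
    identity: float
    linkage: str  # tandem | dispersed
    event_id: int


def _span_distance(a: ExonChain, b: ExonChain) -> int | None:
    if a.chromosome != b.chromosome:
        return None
    (sa, ea), (sb, eb) = a.span, b.span
    if ea < sb:
        return sb - ea - 1
    if eb < sa:
        return sa - eb - 1
    return 0  # overlapping spans


def call_duplications(genes: list[SeqEntry], chains: list[ExonChain],
                      cov: float = 0.8, ident: float = 0.8,
                      linkage_window: int = 25_000,
                      scoring: ScoringScheme | None = None,
                      protein_mode: bool = False
                      ) -> tuple[list[DuplicationPair], int]:
    """Evaluate every unordered pair; returns (pairs, n_events).

    ``n_events`` counts single-linkage clusters of tandem pairs once,
    plus each dispersed pair.
    """
    if len(genes) < 2:
        return [], 0
    if scoring is None:
        scoring = PROTEIN_SCORING if protein_mode else NUCLEOTIDE_SCORING
    chain_of = {c.gene_id: c for c in chains}
    genes = sorted(genes, key=lambda e: e.id)
    # score bound: under a reduced scoring where every penalized column
    # (mismatch or gap) costs c = |mismatch| and matches score M, any
    # alignment with identity > t and m > t*longer matches scores more
    # than m (M - c(1-t)/t) >= t (M - c(1-t)/t) * longer; the reduced
    # optimum is at least the reduced score of the reporting-scheme
    # optimal alignment, so pairs at or below the bound cannot qualify
    if scoring.alphabet == "nucleotide":
        c = abs(scoring.mismatch)
        prescreen = ScoringScheme("nucleotide", match=scoring.match,
                                  mismatch=scoring.mismatch,
                                  gap_open=0.0, gap_extend=c)
        per_match = scoring.match - c * (1 - ident) / ident
        score_factor = max(0.0, per_match * ident)
    else:
        prescreen = None
        score_factor = 0.0  # no uniform match score for matrices
    raw: list[tuple[str, str, float, float]] = []
    n_aligned = 0
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            shorter, longer = sorted((len(a), len(b)))
            if shorter / longer <= min(cov, ident):
                continue
            if score_factor > 0:
                s = global_score(a.sequence, b.sequence, prescreen)
                if s <= score_factor * longer:
                    continue
            aln = global_align(a.sequence, b.sequence, scoring)
            n_aligned += 1
            coverage_longer = aln.aligned_length / longer
            if coverage_longer > cov and aln.identity > ident:
                raw.append((a.id, b.id, coverage_longer, aln.identity))
    logger.info("call_duplications: %d pairs aligned, %d reported",
                n_aligned, len(raw))

    # linkage + event clustering (single linkage over tandem pairs)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    link_of: dict[tuple[str, str], str] = {}
    for ga, gb, _c, _i in raw:
        ca, cb = chain_of.get(ga), chain_of.get(gb)
        dist = _span_distance(ca, cb) if ca and cb else None
        tandem = dist is not None and dist <= linkage_window
        link_of[(ga, gb)] = "tandem" if tandem else "dispersed"
        if tandem:
            parent[find(ga)] = find(gb)

    cluster_ids: dict[str, int] = {}
    pairs: list[DuplicationPair] = []
    next_event = 0
    for ga, gb, c, i in raw:
        if link_of[(ga, gb)] == "tandem":
            root = find(ga)
            if root not in cluster_ids:
                cluster_ids[root] = next_event
                next_event += 1
            ev = cluster_ids[root]
        else:
            ev = next_event
            next_event += 1
        pairs.append(DuplicationPair(ga, gb, c, i, link_of[(ga, gb)], ev))
    n_events = len({p.event_id for p in pairs})
    return pairs, n_events


def annotate_clusters(pairs: list[DuplicationPair],
                      chains: list[ExonChain]) -> list[dict]:
    """Per-event report: member genes, chromosomes, min pairwise distance."""
    chain_of = {c.gene_id: c for c in chains}
    events: dict[int, set[str]] = {}
    for p in pairs:
        events.setdefault(p.event_id, set()).update((p.gene_a, p.gene_b))
    out = []
    for ev in sorted(events):
        members = sorted(events[ev])
        chroms = sorted({chain_of[g].chromosome for g in members
                         if g in chain_of})
        dists = [d for i, a in enumerate(members) for b in members[i + 1:]
                 if a in chain_of and b in chain_of
                 and (d := _span_distance(chain_of[a], chain_of[b])) is not None]
        out.append({
            "event_id": ev,
            "members": members,
            "chromosomes": chroms,
            "min_distance": min(dists) if dists else None,
        })
    return out
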
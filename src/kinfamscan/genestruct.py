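"""Chromosomal location and exon/intron structure from cDNA-to-genome
exact-match chaining.

Each cDNA is located by planting 20-nt seed substrings and searching both
genome orientations; the chromosome/strand with the most seed hits wins
(ties are flagged as ambiguous, not silently resolved). The exon chain is
then the co-linear chain of maximal exact matches between the cDNA and
the locus: genomic gaps >= ``min_intron`` become introns, gaps on the
cDNA side are disallowed, and the chain must cover 100% of the cDNA. An
intron that does not follow the GT..AG rule triggers a warning only —
splice-site conformity is advisory, not a rejection criterion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .seqio import GeneAnnotation, SeqEntry, logger, revcomp

SEED_LENGTH = 20


class StructureError(ValueError):
    pass


@dataclass
class ExonChain:
    """Inferred gene model; coordinates 1-based inclusive, forward strand."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    intron_lengths: list[int]  # forward (genomic) order

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def to_annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.gene_id, self.chromosome,
                              self.exons[0][0], self.exons[-1][1],
                              self.strand, list(self.exons))


def _seed_positions(length: int, step: int = 100) -> list[int]:
    if length < SEED_LENGTH:
        raise StructureError(f"cDNA shorter than seed length {SEED_LENGTH}")
    pos = list(range(0, length - SEED_LENGTH + 1, step))
    last = length - SEED_LENGTH
    if pos[-1] != last:
        pos.append(last)
    return pos


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def locate_gene(cdna: SeqEntry, genome: list[SeqEntry],
                seed_step: int = 100
                ) -> tuple[str, str, tuple[int, int]] | str:
    """Locate a cDNA on the genome by exact seed hits.

    Returns ``(chromosome, strand, approximate_span)`` with a forward
    1-based inclusive span, ``"unplaced"`` when no seed hits anywhere, or
    ``"ambiguous locus"`` when two chromosome/strand combinations tie on
    seed support. Seed hits are clustered (gap > 1500 nt splits clusters)
    so a near-identical duplicate locus on the same chromosome does not
    stretch the span.
    """
    seeds = [cdna.sequence[p:p + SEED_LENGTH]
             for p in _seed_positions(len(cdna.sequence), seed_step)]
    best = None  # (n_seed_hits, chrom, strand, positions)
    tie = False
    for chrom in genome:
        for strand, seq in (("+", chrom.sequence),
                            ("-", revcomp(chrom.sequence))):
            hits: list[int] = []
            n_seed = 0
            for s in seeds:
                if "N" in s:
                    continue
                found = _find_all(seq, s)
                if found:
                    n_seed += 1
                    hits.extend(found)
            if n_seed == 0:
                continue
            # densest cluster of hit positions
            hits.sort()
            clusters: list[list[int]] = [[hits[0]]]
            for h in hits[1:]:
                if h - clusters[-1][-1] > 1500:
                    clusters.append([h])
                else:
                    clusters[-1].append(h)
            cl = max(clusters, key=len)
            key = (n_seed, len(cl))
            if best is None or key > best[0]:
                best = (key, chrom.id, strand, cl, len(chrom.sequence))
                tie = False
            elif key == best[0]:
                tie = True
    if best is None:
        return "unplaced"
    if tie:
        return "ambiguous locus"
    _, chrom_id, strand, cl, chrom_len = best
    lo = max(0, cl[0] - 100)
    hi = min(chrom_len, cl[-1] + SEED_LENGTH + 100)
    if strand == "-":  # positions were on the reverse-complement
        lo, hi = chrom_len - hi, chrom_len - lo
    return chrom_id, strand, (lo + 1, hi)


def infer_exons(cdna: str, locus_sequence: str,
                min_intron: int = 20) -> list[tuple[int, int]]:
    """Exon intervals (0-based half-open, transcript orientation) within
    ``locus_sequence`` whose concatenation equals the cDNA exactly.

    Greedy maximal extension: each exon is extended until the first
    mismatch; the next exon is re-anchored by searching the next 20-nt
    cDNA substring at least ``min_intron`` further along the locus.
    Raises :class:`StructureError` ("unresolvable structure") when the
    chain cannot cover the full cDNA.
    """
    L = len(cdna)
    if L < SEED_LENGTH:
        raise StructureError("cDNA shorter than seed length")
    g = locus_sequence.find(cdna[:SEED_LENGTH])
    if g == -1:
        raise StructureError("unresolvable structure: start seed not found")
    p = 0
    exons: list[tuple[int, int]] = []
    while p < L:
        m = 0
        while (p + m < L and g + m < len(locus_sequence)
               and cdna[p + m] == locus_sequence[g + m]
               and cdna[p + m] != "N"):
            m += 1
        if m == 0:
            raise StructureError("unresolvable structure: zero-length exon")
        exons.append((g, g + m))
        p += m
        if p >= L:
            break
        seed = cdna[p:p + SEED_LENGTH]
        g_next = locus_sequence.find(seed, g + m + min_intron)
        if g_next == -1:
            raise StructureError(
                "unresolvable structure: cannot re-anchor after position "
                f"{p} of the cDNA")
        g = g_next
    if sum(e - s for s, e in exons) != L:
        raise StructureError("unresolvable structure: incomplete coverage")
    for (s0, e0), (s1, _e1) in zip(exons, exons[1:]):
        intron = locus_sequence[e0:s1]
        if not (intron.startswith("GT") and intron.endswith("AG")):
            logger.warning("non-canonical splice sites in intron at %d..%d",
                           e0, s1)
    return exons


def gene_structure(cdna: SeqEntry, genome: list[SeqEntry],
                   min_intron: int = 20, seed_step: int = 100) -> ExonChain:
    """Locate the cDNA and derive its exon chain in forward coordinates."""
    loc = locate_gene(cdna, genome, seed_step)
    if isinstance(loc, str):
        raise StructureError(f"{cdna.id}: {loc}")
    chrom_id, strand, (lo, hi) = loc
    chrom = next(c for c in genome if c.id == chrom_id)
    window = chrom.sequence[lo - 1:hi]
    if strand == "-":
        window = revcomp(window)
    local = infer_exons(cdna.sequence, window, min_intron)
    W = len(window)
    if strand == "+":
        exons = [(lo + s, lo - 1 + e) for s, e in local]
    else:
        # transcript-orientation offsets map back through the window flip
        exons = sorted((lo + (W - e), lo - 1 + (W - s)) for s, e in local)
    introns = [exons[i + 1][0] - exons[i][1] - 1 for i in range(len(exons) - 1)]
    return ExonChain(cdna.id, chrom_id, strand, exons, introns)


def gene_structures(cdnas: list[SeqEntry], genome: list[SeqEntry],
                    min_intron: int = 20, seed_step: int = 100
                    ) -> tuple[list[ExonChain], dict[str, str]]:
    """Batch driver; failures are collected, not fatal."""
    chains: list[ExonChain] = []
    failures: dict[str, str] = {}
    for cdna in cdnas:
        try:
            chains.append(gene_structure(cdna, genome, min_intron, seed_step))
        except StructureError as exc:
            failures[cdna.id] = str(exc)
    logger.info("gene_structures: %d resolved, %d failed",
                len(chains), len(failures))
    return chains, failures


def chromosome_distribution(chains: list[ExonChain],
                            subfamilies: dict[str, str] | None = None
                            ) -> tuple[dict[str, int], dict[str, set[str]]]:
    """Per-chromosome gene counts and per-chromosome subfamily presence."""
    counts = Counter(c.chromosome for c in chains)
    presence: dict[str, set[str]] = {}
    if subfamilies:
        for c in chains:
            fam = subfamilies.get(c.gene_id)
            if fam:
                presence.setdefault(c.chromosome, set()).add(fam)
    return dict(sorted(counts.items())), presence
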
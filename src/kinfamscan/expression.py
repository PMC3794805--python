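"""Transcript quantification by unique exact read matching and RPKM.

A read is assigned to a transcript when the read (or its reverse
complement — library strandedness is not assumed) occurs as an exact
substring of the transcript and of no other transcript; multi-mapping
reads are discarded entirely. Reads shorter than the 20-nt signature
minimum are rejected. Expression is reported as

    RPKM = 1e6 * C / (N * L / 1e3)

with C the transcript's uniquely-aligned read count, N the sample total
of uniquely-aligned reads and L the transcript length in bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import SeqEntry, logger, revcomp

MIN_READ_LENGTH = 20
_PREFIX = 20  # k-mer length for the candidate index


class ExpressionError(ValueError):
    pass


class TranscriptIndex:
    """Exact-substring membership index over both orientations."""

    def __init__(self, transcripts: list[SeqEntry],
                 min_read_length: int = MIN_READ_LENGTH) -> None:
        if not transcripts:
            raise ExpressionError("no transcripts to index")
        self.min_read_length = min_read_length
        self.seqs: dict[str, str] = {t.id: t.sequence for t in transcripts}
        self.rcs: dict[str, str] = {t.id: revcomp(t.sequence)
                                    for t in transcripts}
        self.lengths: dict[str, int] = {t.id: len(t.sequence)
                                        for t in transcripts}
        self._kmers: dict[str, set[str]] = {}
        for tid, seq in self.seqs.items():
            for s in (seq, self.rcs[tid]):
                for i in range(len(s) - _PREFIX + 1):
                    self._kmers.setdefault(s[i:i + _PREFIX], set()).add(tid)
        self.n_rejected_short = 0

    def query(self, read: str) -> set[str] | None:
        """Transcript ids containing the read in either orientation;
        None when the read is shorter than the minimum."""
        if len(read) < self.min_read_length:
            self.n_rejected_short += 1
            return None
        cands = self._kmers.get(read[:_PREFIX], ())
        hits = {tid for tid in cands
                if read in self.seqs[tid] or read in self.rcs[tid]}
        return hits


def build_index(transcripts: list[SeqEntry],
                min_read_length: int = MIN_READ_LENGTH) -> TranscriptIndex:
    return TranscriptIndex(transcripts, min_read_length)


def count_unique(reads: list[SeqEntry], index: TranscriptIndex
                 ) -> tuple[dict[str, int], int]:
    """Per-transcript unique counts C and the sample total N = sum(C)."""
    C = {tid: 0 for tid in index.seqs}
    rejected = 0
    for read in reads:
        hits = index.query(read.sequence)
        if hits is None:
            rejected += 1
            continue
        if len(hits) == 1:
            C[next(iter(hits))] += 1
    N = sum(C.values())
    if rejected:
        logger.info("count_unique: %d reads below %d nt rejected",
                    rejected, index.min_read_length)
    return C, N


def rpkm(C: int, N: int, L: int) -> float:
    """Reads per kilobase of transcript per million uniquely mapped reads."""
    if L <= 0:
        raise ExpressionError("transcript length must be positive")
    if C < 0 or N < C:
        raise ExpressionError("need N >= C >= 0")
    if N == 0:
        return 0.0
    return 1e6 * C / (N * L / 1e3)


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    tissue: str
    C: int
    N: int
    L: int
    rpkm: float


def quantify(transcripts: list[SeqEntry],
             reads_by_tissue: dict[str, list[SeqEntry]],
             min_read_length: int = MIN_READ_LENGTH) -> list[ExpressionRecord]:
    """Count + RPKM for every transcript in every tissue sample."""
    index = build_index(transcripts, min_read_length)
    records: list[ExpressionRecord] = []
    for tissue, reads in reads_by_tissue.items():
        C, N = count_unique(reads, index)
        for tid in sorted(C):
            L = index.lengths[tid]
            records.append(ExpressionRecord(tid, tissue, C[tid], N, L,
                                            rpkm(C[tid], N, L)))
        logger.info("quantify: tissue %s N=%d of %d reads", tissue, N,
                    len(reads))
    return records


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    expressed: bool
    preference: str  # higher_0DPA | higher_3DPA | equal/NA


def call_expression(records: list[ExpressionRecord], min_reads: int = 1,
                    ovule0: str = "ovule0", ovule3: str = "ovule3"
                    ) -> list[ExpressionCall]:
    """Expressed iff any tissue has C >= min_reads; ovule preference by
    strict RPKM inequality (ties -> equal/NA). Errors when a gene is
    missing a tissue."""
    by_gene: dict[str, dict[str, ExpressionRecord]] = {}
    tissues = {r.tissue for r in records}
    for r in records:
        by_gene.setdefault(r.transcript_id, {})[r.tissue] = r
    calls = []
    for gid in sorted(by_gene):
        recs = by_gene[gid]
        if set(recs) != tissues or not {ovule0, ovule3} <= set(recs):
            raise ExpressionError(f"missing tissue for {gid}")
        expressed = any(r.C >= min_reads for r in recs.values())
        r0, r3 = recs[ovule0].rpkm, recs[ovule3].rpkm
        if r0 > r3:
            pref = "higher_0DPA"
        elif r3 > r0:
            pref = "higher_3DPA"
        else:
            pref = "equal/NA"
        calls.append(ExpressionCall(gid, expressed, pref))
    return calls
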
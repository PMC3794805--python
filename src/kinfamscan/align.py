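"""Pairwise alignment engines used by the screening, duplication and
phylogeny stages.

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with affine
gaps, computed by :class:`Bio.Align.PairwiseAligner`. Statistics follow
fixed definitions used throughout the pipeline:

* ``identity`` — matching columns / all alignment columns (double-gap
  columns cannot occur in a pairwise alignment); for local mode the
  columns are those of the local hit only.
* ``aligned_length`` — columns in which *both* sequences carry a residue.
* ``coverage_x`` — aligned (non-gap) residues of sequence x divided by its
  full length.

Gap cost convention: a gap of length L costs ``gap_open + gap_extend * L``.

Defaults: BLOSUM62 with gap open 10 / extend 1 for proteins; match 2 /
mismatch -3 / gap open 5 / extend 2 for nucleotides. Both are configurable
per call. ``N`` in nucleotide input scores as a mismatch against every
base, itself included.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import NUCLEOTIDE_ALPHABET, PROTEIN_ALPHABET


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution + affine-gap parameters for one alphabet."""

    alphabet: str  # "protein" | "nucleotide"
    matrix_name: str | None = None  # named substitution matrix (protein)
    match: float = 2.0  # used when matrix_name is None
    mismatch: float = -3.0
    gap_open: float = 10.0
    gap_extend: float = 1.0


PROTEIN_SCORING = ScoringScheme("protein", matrix_name="BLOSUM62",
                                gap_open=10.0, gap_extend=1.0)
NUCLEOTIDE_SCORING = ScoringScheme("nucleotide", match=2.0, mismatch=-3.0,
                                   gap_open=5.0, gap_extend=2.0)


@dataclass(frozen=True)
class PairwiseAlignment:
    """An aligned pair with the statistics the pipeline thresholds use."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    aligned_length: int
    coverage_a: float
    coverage_b: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def infer_alphabet(seq: str) -> str:
    """'nucleotide' if the sequence fits ACGTN, else 'protein'."""
    chars = set(seq)
    if chars <= NUCLEOTIDE_ALPHABET:
        return "nucleotide"
    if chars <= PROTEIN_ALPHABET:
        return "protein"
    raise AlignmentError(f"sequence contains non-residue characters: "
                         f"{sorted(chars - PROTEIN_ALPHABET - NUCLEOTIDE_ALPHABET)}")


@lru_cache(maxsize=8)
def _nt_matrix(match: float, mismatch: float):
    alpha = "ACGTN"
    arr = substitution_matrices.Array(alpha, dims=2)
    for x in alpha:
        for y in alpha:
            if x == y and x != "N":
                arr[x, y] = match
            else:
                arr[x, y] = mismatch
    return arr


@lru_cache(maxsize=8)
def _named_matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(scoring: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scoring.alphabet == "protein":
        aligner.substitution_matrix = _named_matrix(scoring.matrix_name or "BLOSUM62")
    else:
        aligner.substitution_matrix = _nt_matrix(scoring.match, scoring.mismatch)
    # our convention: gap of length L costs open + extend * L
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _check_inputs(a: str, b: str, scoring: ScoringScheme | None) -> ScoringScheme:
    if not a or not b:
        raise AlignmentError("empty sequence")
    if scoring is not None:
        # explicit scheme: just validate the characters against it
        allowed = (NUCLEOTIDE_ALPHABET if scoring.alphabet == "nucleotide"
                   else PROTEIN_ALPHABET)
        bad = (set(a) | set(b)) - allowed
        if bad:
            raise AlignmentError(
                f"characters {sorted(bad)} invalid for {scoring.alphabet} "
                "scoring")
        return scoring
    alpha_a, alpha_b = infer_alphabet(a), infer_alphabet(b)
    # every ACGTN string is also a valid peptide, so a protein-vs-
    # nucleotide mix is only detectable heuristically: one side ACGTN-only
    # while the other carries protein-specific residues
    if alpha_a != alpha_b:
        raise AlignmentError("mixed alphabets: cannot align nucleotide "
                             "against protein sequence")
    return (NUCLEOTIDE_SCORING if alpha_a == "nucleotide"
            else PROTEIN_SCORING)


def _stats(aligned_a: str, aligned_b: str, score: float,
           len_a: int, len_b: int, nucleotide: bool) -> PairwiseAlignment:
    cols = len(aligned_a)
    # N is an ambiguity code for nucleotides (never a match) but a
    # regular residue (asparagine) for proteins
    excluded = "-N" if nucleotide else "-"
    matches = sum(1 for x, y in zip(aligned_a, aligned_b)
                  if x == y and x not in excluded)
    both = sum(1 for x, y in zip(aligned_a, aligned_b)
               if x != "-" and y != "-")
    res_a = cols - aligned_a.count("-")
    res_b = cols - aligned_b.count("-")
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        identity=matches / cols if cols else 0.0,
        aligned_length=both,
        coverage_a=res_a / len_a,
        coverage_b=res_b / len_b,
    )


def _gapped_strings(alignment) -> tuple[str, str]:
    text_a, text_b = alignment[0], alignment[1]
    return str(text_a), str(text_b)


def global_align(a: str, b: str,
                 scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch alignment of the full sequences."""
    scoring = _check_inputs(a, b, scoring)
    aligner = _make_aligner(scoring, "global")
    alignment = next(iter(aligner.align(a, b)))
    ga, gb = _gapped_strings(alignment)
    return _stats(ga, gb, alignment.score, len(a), len(b),
                  scoring.alphabet == "nucleotide")


def local_align(a: str, b: str,
                scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Smith–Waterman local alignment; the empty alignment (score
    0) is returned when no positive-scoring segment pair exists."""
    scoring = _check_inputs(a, b, scoring)
    aligner = _make_aligner(scoring, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return PairwiseAlignment("", "", 0.0, 0.0, 0, 0.0, 0.0)
    alignment = next(iter(aligner.align(a, b)))
    ga, gb = _gapped_strings(alignment)
    return _stats(ga, gb, alignment.score, len(a), len(b),
                  scoring.alphabet == "nucleotide")


def global_score(a: str, b: str,
                 scoring: ScoringScheme | None = None) -> float:
    """Optimal global alignment score only (no traceback; much faster)."""
    scoring = _check_inputs(a, b, scoring)
    aligner = _make_aligner(scoring, "global")
    return float(aligner.score(a, b))


def identity_matrix(seqs: list[str],
                    scoring: ScoringScheme | None = None) -> np.ndarray:
    """Symmetric matrix of global-alignment identities (diagonal 1)."""
    n = len(seqs)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = global_align(seqs[i], seqs[j], scoring).identity
    return out
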
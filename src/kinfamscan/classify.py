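"""Subfamily classification of accepted kinases.

Plant MAP kinase kinase kinases fall into three subfamilies that are
recognizable from short conserved signatures around the activation
segment, plus the position of the kinase domain within the protein:

* ZIK — the literal signature ``GTPEFMAPELY``; kinase domain usually
  N-terminal.
* MEKK — consensus ``G-[TS]-P-x-[WF]-M-A-P-E-V``; kinase domain anywhere.
* Raf — the looser consensus ``G-T-x-x-[WY]-M-A-P-E-[LV]``; kinase domain
  usually C-terminal behind a long regulatory region.

The three signature classes overlap (a MEKK-style match can also satisfy
the Raf consensus), so calls use the fixed precedence ZIK > MEKK > Raf
(most specific first) and flag ambiguity instead of discarding it.
``X``/``x`` in a consensus means any of the 20 standard residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .identify import PrositePattern, parse_prosite
from .seqio import SeqEntry

ZIK_SIGNATURE = "G-T-P-E-F-M-A-P-E-L-Y"
MEKK_SIGNATURE = "G-[TS]-P-x-[WF]-M-A-P-E-V"
RAF_SIGNATURE = "G-T-x-x-[WY]-M-A-P-E-[LV]"

SUBFAMILIES = ("ZIK", "MEKK", "Raf")


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    subfamily: str  # ZIK | MEKK | Raf | unclassified
    signature_hit: tuple[str, int] | None  # (matched substring, position)
    domain_position: str  # N-terminal | central | C-terminal
    ambiguous: bool


def compile_signatures() -> dict[str, PrositePattern]:
    """The three subfamily signature matchers, in precedence order."""
    return {
        "ZIK": parse_prosite(ZIK_SIGNATURE, "ZIK"),
        "MEKK": parse_prosite(MEKK_SIGNATURE, "MEKK"),
        "Raf": parse_prosite(RAF_SIGNATURE, "Raf"),
    }


def domain_position_label(span: tuple[int, int] | None, length: int) -> str:
    """Thirds rule on the domain midpoint (half-open span, 0-based)."""
    if span is None:
        span = (0, length)
    mid = (span[0] + span[1]) / 2
    if mid < length / 3:
        return "N-terminal"
    if mid >= 2 * length / 3:
        return "C-terminal"
    return "central"


def classify_protein(protein: SeqEntry,
                     kinase_domain_span: tuple[int, int] | None = None,
                     signatures: dict[str, PrositePattern] | None = None
                     ) -> SubfamilyCall:
    """Assign a subfamily by signature match, precedence ZIK > MEKK > Raf.

    ``ambiguous`` is set when two or more signature classes match; the
    precedence winner is still reported. A protein matching no signature is
    ``unclassified``.
    """
    if signatures is None:
        signatures = compile_signatures()
    seq = protein.sequence
    hits: dict[str, tuple[str, int]] = {}
    for fam in SUBFAMILIES:
        spans = signatures[fam].match_spans(seq)
        if spans:
            s, e = spans[0]
            hits[fam] = (seq[s:e], s)
    label = next((fam for fam in SUBFAMILIES if fam in hits), "unclassified")
    return SubfamilyCall(
        protein_id=protein.id,
        subfamily=label,
        signature_hit=hits.get(label),
        domain_position=domain_position_label(kinase_domain_span, len(seq)),
        ambiguous=len(hits) > 1,
    )


def kinase_domain_span(sequence: str,
                       patterns: list[PrositePattern]) -> tuple[int, int] | None:
    """Operational kinase-domain span: leftmost hallmark match start to
    rightmost hallmark match end (half-open)."""
    starts: list[int] = []
    ends: list[int] = []
    for pat in patterns:
        for s, e in pat.match_spans(sequence):
            starts.append(s)
            ends.append(e)
    if not starts:
        return None
    return (min(starts), max(ends))


def classify_all(proteins: list[SeqEntry],
                 hallmark_patterns: list[PrositePattern] | None = None
                 ) -> list[SubfamilyCall]:
    signatures = compile_signatures()
    calls = []
    for p in proteins:
        span = (kinase_domain_span(p.sequence, hallmark_patterns)
                if hallmark_patterns else None)
        calls.append(classify_protein(p, span, signatures))
    return calls


def summarize_subfamilies(calls: list[SubfamilyCall]) -> dict[str, int]:
    """Counts per subfamily (including 'unclassified'); sums to len(calls)."""
    counts = Counter(c.subfamily for c in calls)
    return {fam: counts.get(fam, 0) for fam in (*SUBFAMILIES, "unclassified")}
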
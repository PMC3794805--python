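"""The identification funnel: homology screen at >=50% identity,
self-alignment redundancy removal, and kinase hallmark motif validation.

The hallmark motifs (a protein kinase ATP-binding region, a
serine/threonine kinase active site and a catalytic kinase-domain pattern)
are expressed in PROSITE pattern grammar and loaded from the packaged
``data/hallmarks.yaml`` so users can substitute their own definitions or a
true profile scanner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .align import ScoringScheme, global_align, local_align
from .seqio import PROTEIN_ALPHABET, SeqEntry, logger

_AA = "ACDEFGHIKLMNPQRSTVWY"


class PrositeSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class PrositePattern:
    """A compiled PROSITE-grammar pattern.

    Supported grammar: residue letters, ``x`` (any residue), ``[..]``
    (one-of), ``{..}`` (none-of), ``(n)`` / ``(n,m)`` repetition, ``-``
    separators and the ``<`` / ``>`` terminal anchors.
    """

    name: str
    pattern: str
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    def match_positions(self, sequence: str) -> list[int]:
        """All (overlapping) match start positions in the sequence."""
        return [m.start() for m in self._regex.finditer(sequence)]

    def match_spans(self, sequence: str) -> list[tuple[int, int]]:
        """All (start, end) half-open spans of overlapping matches."""
        return [(m.start(), m.start() + len(m.group(1)))
                for m in self._regex.finditer(sequence)]

    def matches(self, sequence: str) -> bool:
        return self._regex.search(sequence) is not None


def _tokenize(pattern: str) -> list[str]:
    # split on '-' separators, respecting brackets (PROSITE puts '-' only
    # between elements, never inside [..]/{..}, so a plain split is safe)
    return [t for t in pattern.strip().rstrip(".").split("-") if t]


def parse_prosite(pattern: str, name: str = "") -> PrositePattern:
    """Compile a PROSITE-grammar pattern into an overlapping matcher.

    Raises :class:`PrositeSyntaxError` naming the offending element
    position on malformed input.
    """
    tokens = _tokenize(pattern)
    if not tokens:
        raise PrositeSyntaxError("empty pattern")
    parts: list[str] = []
    anchor_start = anchor_end = False
    elem_re = re.compile(
        r"^(?:(?P<res>[A-Za-z])|(?P<any>x)|\[(?P<one>[A-Z]+)\]|\{(?P<none>[A-Z]+)\})"
        r"(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$"
    )
    for pos, tok in enumerate(tokens):
        if pos == 0 and tok.startswith("<"):
            anchor_start = True
            tok = tok[1:]
        if pos == len(tokens) - 1 and tok.endswith(">"):
            anchor_end = True
            tok = tok[:-1]
        m = elem_re.match(tok)
        if m is None:
            raise PrositeSyntaxError(
                f"malformed PROSITE element {tok!r} at position {pos}"
            )
        if m.group("res"):
            res = m.group("res").upper()
            if res == "X":
                core = f"[{_AA}]"
            elif res in PROTEIN_ALPHABET:
                core = res
            else:
                raise PrositeSyntaxError(
                    f"unknown residue {res!r} at position {pos}"
                )
        elif m.group("any"):
            core = f"[{_AA}]"
        elif m.group("one"):
            core = f"[{m.group('one')}]"
        else:
            excluded = set(m.group("none"))
            allowed = "".join(sorted(set(_AA) - excluded))
            core = f"[{allowed}]"
        if m.group("n"):
            if m.group("m"):
                core += f"{{{m.group('n')},{m.group('m')}}}"
            else:
                core += f"{{{m.group('n')}}}"
        parts.append(core)
    body = "".join(parts)
    if anchor_start:
        body = "^" + body
    if anchor_end:
        body += "$"
    # lookahead wrapper reports overlapping matches and captures the span
    regex = re.compile(f"(?=({body}))")
    return PrositePattern(name=name or pattern, pattern=pattern, _regex=regex)


def load_hallmarks(path: str | Path | None = None) -> list[PrositePattern]:
    """Load the hallmark PROSITE patterns from YAML (packaged default)."""
    if path is None:
        text = resources.files("kinfamscan.data").joinpath("hallmarks.yaml").read_text()
        cfg = yaml.safe_load(text)
    else:
        cfg = yaml.safe_load(Path(path).read_text())
    return [parse_prosite(h["pattern"], h["name"]) for h in cfg["hallmarks"]]


@dataclass
class CandidateReport:
    """Per-candidate record of every funnel decision."""

    protein_id: str
    best_query_id: str | None = None
    best_identity: float = 0.0
    passed_identity: bool = False
    matched_hallmarks: set[str] = field(default_factory=set)
    accepted: bool = False
    redundant_with: str | None = None


def screen_by_identity(candidates: list[SeqEntry], queries: list[SeqEntry],
                       threshold: float = 0.50,
                       scoring: ScoringScheme | None = None) -> list[CandidateReport]:
    """Local-alignment identity screen of candidates against the query set.

    ``best_identity`` is the maximum, over queries, of the identity computed
    across the optimal local alignment's columns (BLASTP-hit semantics).
    """
    if not queries:
        raise ValueError("at least one query sequence required")
    reports: list[CandidateReport] = []
    for cand in candidates:
        best_q, best_i = None, 0.0
        for q in queries:
            ident = local_align(cand.sequence, q.sequence, scoring).identity
            if ident > best_i:
                best_q, best_i = q.id, ident
        reports.append(CandidateReport(
            protein_id=cand.id, best_query_id=best_q, best_identity=best_i,
            passed_identity=best_i >= threshold,
        ))
    n_pass = sum(r.passed_identity for r in reports)
    logger.info("screen_by_identity: %d/%d candidates pass %.0f%%",
                n_pass, len(candidates), 100 * threshold)
    return reports


def remove_redundancy(passed: list[SeqEntry], coverage_min: float = 0.98,
                      identity_min: float = 0.98,
                      scoring: ScoringScheme | None = None
                      ) -> tuple[list[SeqEntry], dict[str, str]]:
    """Collapse near-identical database duplicates.

    Two sequences are linked when their global alignment has identity >=
    ``identity_min`` and mutual coverage >= ``coverage_min`` (coverage of a
    sequence = columns where both carry a residue / that sequence's
    length). Single-linkage clusters are reduced to their longest member
    (ties to the lexicographically smallest id). Returns the kept entries
    (input order) and a map redundant_id -> keeper_id.

    The result is independent of input order: linkage is a symmetric
    relation evaluated over all pairs.
    """
    n = len(passed)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = passed[i], passed[j]
            ratio = min(len(a), len(b)) / max(len(a), len(b))
            if ratio < coverage_min:  # coverage bound: aligned_length <= shorter
                continue
            aln = global_align(a.sequence, b.sequence, scoring)
            cov_a = aln.aligned_length / len(a)
            cov_b = aln.aligned_length / len(b)
            if aln.identity >= identity_min and min(cov_a, cov_b) >= coverage_min:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    redundant: dict[str, str] = {}
    kept_idx: set[int] = set()
    for members in clusters.values():
        keeper = min(members, key=lambda k: (-len(passed[k]), passed[k].id))
        kept_idx.add(keeper)
        for m in members:
            if m != keeper:
                redundant[passed[m].id] = passed[keeper].id
    kept = [e for i, e in enumerate(passed) if i in kept_idx]
    logger.info("remove_redundancy: kept %d of %d", len(kept), n)
    return kept, redundant


def validate_hallmarks(proteins: list[SeqEntry],
                       patterns: list[PrositePattern]) -> dict[str, set[str]]:
    """Match every required hallmark pattern; returns id -> matched names."""
    if not patterns:
        raise ValueError("no hallmarks configured")
    out: dict[str, set[str]] = {}
    for p in proteins:
        out[p.id] = {pat.name for pat in patterns if pat.matches(p.sequence)}
    return out


def run_identification(candidates: list[SeqEntry], queries: list[SeqEntry],
                       patterns: list[PrositePattern],
                       identity_threshold: float = 0.50,
                       redundancy_identity: float = 0.98,
                       redundancy_coverage: float = 0.98,
                       scoring: ScoringScheme | None = None
                       ) -> tuple[list[SeqEntry], list[CandidateReport]]:
    """Full funnel: identity screen -> redundancy removal -> hallmark check.

    A candidate is accepted iff it passes the identity screen, is not
    redundant with a kept sequence, and matches every hallmark pattern.
    """
    reports = screen_by_identity(candidates, queries, identity_threshold, scoring)
    by_id = {r.protein_id: r for r in reports}
    passed = [c for c, r in zip(candidates, reports) if r.passed_identity]
    kept, redundant = remove_redundancy(
        passed, redundancy_coverage, redundancy_identity, scoring)
    for rid, keeper in redundant.items():
        by_id[rid].redundant_with = keeper
    hallmark_hits = validate_hallmarks(kept, patterns)
    required = {p.name for p in patterns}
    accepted: list[SeqEntry] = []
    for entry in kept:
        rep = by_id[entry.id]
        rep.matched_hallmarks = hallmark_hits[entry.id]
        if rep.matched_hallmarks == required:
            rep.accepted = True
            accepted.append(entry)
    logger.info("run_identification: %d candidates -> %d accepted",
                len(candidates), len(accepted))
    return accepted, reports
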
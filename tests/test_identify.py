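"""PROSITE pattern grammar and the identification funnel."""

import itertools

import numpy as np
import pytest

from kinfamscan.identify import (PrositeSyntaxError, load_hallmarks,
                                 parse_prosite, remove_redundancy,
                                 run_identification, screen_by_identity,
                                 validate_hallmarks)
from kinfamscan.seqio import SeqEntry
from kinfamscan.align import global_align


class TestPrositeGrammar:
    def test_literal_signature(self):
        pat = parse_prosite("G-T-P-E-F-M-A-P-E-L-Y")
        assert pat.match_positions("GTPEFMAPELY") == [0]
        assert pat.match_positions("XXGTPEFMAPELYXX".replace("X", "A")) == [2]

    def test_one_of_class_and_x_repeat(self):
        pat = parse_prosite("[AG]-x(2)-K")
        assert pat.matches("ACDK")
        assert not pat.matches("PCDK")

    def test_bounded_repeat(self):
        pat = parse_prosite("x(2,3)-W")
        assert pat.matches("AAW")
        assert pat.matches("AAAW")
        assert not pat.matches("AW")

    def test_none_of_class(self):
        pat = parse_prosite("{P}-G")
        assert pat.matches("AG")
        assert not pat.matches("PG")

    def test_anchors(self):
        assert parse_prosite("<M-x-K").matches("MAKLL")
        assert not parse_prosite("<M-x-K").matches("AMAKLL")
        assert parse_prosite("K-R>").matches("AAKR")
        assert not parse_prosite("K-R>").matches("AAKRA")

    def test_overlapping_matches_reported(self):
        pat = parse_prosite("A-x-A")
        assert pat.match_positions("AAAAA") == [0, 1, 2]

    @pytest.mark.parametrize("bad", ["", "G-[", "G-(2)", "G-x(2,", "G-#"])
    def test_malformed_grammar_errors(self, bad):
        with pytest.raises(PrositeSyntaxError):
            parse_prosite(bad)

    def test_error_names_position(self):
        with pytest.raises(PrositeSyntaxError, match="position 1"):
            parse_prosite("G-[XY")


class TestScreen:
    def test_identical_candidate_passes_at_one(self):
        q = SeqEntry("q", "", "MKVLAWHEMKVLAWHEMKVL")
        reports = screen_by_identity([SeqEntry("c", "", q.sequence)], [q])
        assert reports[0].best_identity == 1.0
        assert reports[0].passed_identity

    def test_threshold_zero_passes_everything(self):
        q = [SeqEntry("q", "", "MKVLAWHEMKVLAWHEMKVL")]
        cands = [SeqEntry("c", "", "WWWWHHHHPPPPGGGGYYYY")]
        assert screen_by_identity(cands, q, threshold=0.0)[0].passed_identity

    def test_empty_candidates_empty_report(self):
        assert screen_by_identity(
            [], [SeqEntry("q", "", "MKVLAWHEMKVL")]) == []

    def test_no_queries_errors(self):
        with pytest.raises(ValueError):
            screen_by_identity([SeqEntry("c", "", "MKVL")], [])


def brute_force_clusters(entries, cov_min, id_min):
    """Independent oracle: explicit pairwise linkage + transitive closure."""
    n = len(entries)
    adj = {i: {i} for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(entries[i].sequence, entries[j].sequence)
        cov_i = aln.aligned_length / len(entries[i])
        cov_j = aln.aligned_length / len(entries[j])
        if aln.identity >= id_min and min(cov_i, cov_j) >= cov_min:
            adj[i].add(j)
            adj[j].add(i)
    clusters = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return set(clusters)


class TestRedundancy:
    base = "MKVLAWHEDRNCQGILFPSTYMKVLAWHEDRNCQGILFPSTY"

    def test_identical_entries_collapse(self):
        entries = [SeqEntry("a", "", self.base), SeqEntry("b", "", self.base)]
        kept, redundant = remove_redundancy(entries)
        assert [e.id for e in kept] == ["a"]  # tie -> smallest id
        assert redundant == {"b": "a"}

    def test_distinct_entries_all_kept(self):
        entries = [SeqEntry("a", "", self.base),
                   SeqEntry("b", "", "WWWWHHHHPPPPGGGGYYYYWWWWHHHH")]
        kept, redundant = remove_redundancy(entries)
        assert len(kept) == 2 and not redundant

    def test_chain_linkage_matches_brute_force(self):
        # a~b and b~c at ~99% identity, a vs c slightly lower: single-
        # linkage must still cluster all three (longest kept)
        a = self.base * 3
        b = a[:60] + "A" + a[61:]
        c = b[:80] + "G" + b[81:]
        entries = [SeqEntry("a", "", a), SeqEntry("b", "", b),
                   SeqEntry("c", "", c)]
        kept, redundant = remove_redundancy(entries, 0.95, 0.97)
        oracle = brute_force_clusters(entries, 0.95, 0.97)
        assert oracle == {frozenset({0, 1, 2})}
        assert len(kept) == 1
        assert set(redundant) == {e.id for e in entries} - {kept[0].id}

    def test_order_independent(self):
        entries = [SeqEntry("a", "", self.base),
                   SeqEntry("b", "", self.base),
                   SeqEntry("c", "", "WWWWHHHHPPPPGGGGYYYYWWWWHHHH")]
        kept1, _ = remove_redundancy(entries)
        kept2, _ = remove_redundancy(entries[::-1])
        assert {e.id for e in kept1} == {e.id for e in kept2}


class TestHallmarks:
    def test_planted_family_protein_matches_all(self, small_dataset):
        patterns = load_hallmarks()
        truth = small_dataset.truth
        prot = next(iter(truth.genes.values())).protein
        hits = validate_hallmarks([SeqEntry("p", "", prot)], patterns)
        assert hits["p"] == {p.name for p in patterns}

    def test_near_miss_decoy_rejected(self, small_dataset):
        patterns = load_hallmarks()
        truth = small_dataset.truth
        near = {e.id: e for e in small_dataset.candidates
                if e.id in set(truth.near_miss_ids)}
        hits = validate_hallmarks(list(near.values()), patterns)
        required = {p.name for p in patterns}
        assert all(h != required for h in hits.values())

    def test_poly_a_matches_nothing(self):
        hits = validate_hallmarks([SeqEntry("p", "", "A" * 200)],
                                  load_hallmarks())
        assert hits["p"] == set()

    def test_empty_pattern_list_errors(self):
        with pytest.raises(ValueError, match="no hallmarks"):
            validate_hallmarks([SeqEntry("p", "", "AAA")], [])


class TestFunnel:
    def test_funnel_monotone_in_threshold(self, small_dataset):
        ds = small_dataset
        patterns = load_hallmarks()
        sizes = []
        for thr in (0.3, 0.5, 0.7, 0.95):
            accepted, _ = run_identification(
                ds.candidates, ds.truth.queries, patterns,
                identity_threshold=thr)
            sizes.append(len(accepted))
        assert sizes == sorted(sizes, reverse=True)

    def test_small_profile_exact_recovery(self, small_dataset):
        ds = small_dataset
        accepted, reports = run_identification(
            ds.candidates, ds.truth.queries, load_hallmarks())
        assert {e.id for e in accepted} == set(ds.truth.genes)

    def test_random_decoys_never_accepted(self, small_dataset):
        """Spurious short local hits may clear the naive 50% screen, but
        hallmark validation removes every non-kinase decoy."""
        ds = small_dataset
        accepted, reports = run_identification(
            ds.candidates, ds.truth.queries, load_hallmarks())
        decoys = set(ds.truth.decoy_ids)
        assert all(e.id not in decoys for e in accepted)
        # ...and the near-miss decoys do pass the screen (they are real
        # ancestor-derived kinase-like sequences)
        near = set(ds.truth.near_miss_ids)
        by_id = {r.protein_id: r for r in reports}
        assert all(by_id[d].passed_identity for d in near)
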
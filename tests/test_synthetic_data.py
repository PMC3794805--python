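"""Generator invariants: determinism, planted-motif survival, truth-table
consistency, genome construction and read realization."""

import numpy as np
import pytest

from conftest import small_config
from kinfamscan.classify import compile_signatures
from kinfamscan.identify import load_hallmarks
from kinfamscan.seqio import revcomp
from kinfamscan.synthetic_data import (GeneratorConfig, GeneratorError,
                                       TruthTable, generate_dataset,
                                       generate_proteome, paper_profile_config,
                                       reverse_translate, simulate_reads,
                                       write_dataset)


class TestConfig:
    def test_negative_counts_rejected(self):
        with pytest.raises(GeneratorError):
            GeneratorConfig(n_zik=-1)

    def test_read_length_floor(self):
        with pytest.raises(GeneratorError, match="read_length"):
            GeneratorConfig(read_length=19)

    def test_packaged_profile_matches_published_composition(self):
        cfg = paper_profile_config(seed=0)
        assert (cfg.n_zik, cfg.n_mekk, cfg.n_raf) == (12, 22, 44)
        assert cfg.n_family - cfg.n_unexpressed == 60
        assert cfg.duplication_pairs == 12


class TestProteome:
    def test_deterministic_given_seed(self):
        c1, t1 = generate_proteome(small_config(seed=9))
        c2, t2 = generate_proteome(small_config(seed=9))
        assert c1 == c2
        assert {g: t.protein for g, t in t1.genes.items()} == \
            {g: t.protein for g, t in t2.genes.items()}

    def test_different_seeds_differ(self):
        c1, _ = generate_proteome(small_config(seed=9))
        c2, _ = generate_proteome(small_config(seed=10))
        assert c1 != c2

    def test_single_zik_protein(self):
        cfg = small_config(n_zik=1, n_mekk=0, n_raf=0, n_decoys=0,
                           n_unexpressed=0, duplication_pairs=0,
                           tandem_pairs=0,
                           expression={"raf_higher_0dpa": 0,
                                       "raf_higher_3dpa": 0})
        cands, truth = generate_proteome(cfg)
        assert len(cands) == 1
        assert "GTPEFMAPELY" in cands[0].sequence

    def test_signatures_survive_mutation(self, small_dataset):
        sigs = compile_signatures()
        for g, t in small_dataset.truth.genes.items():
            assert sigs[t.subfamily].matches(t.protein), g

    def test_decoys_never_satisfy_all_hallmarks(self, small_dataset):
        patterns = load_hallmarks()
        required = {p.name for p in patterns}
        decoys = {e.id: e for e in small_dataset.candidates
                  if e.id in set(small_dataset.truth.decoy_ids)}
        for d in decoys.values():
            matched = {p.name for p in patterns if p.matches(d.sequence)}
            assert matched != required, d.id

    def test_duplication_partners_symmetric(self, small_dataset):
        small_dataset.truth.validate()
        pairs = small_dataset.truth.duplication_pairs()
        assert len(pairs) == 2

    def test_benchmark_split_planted(self):
        cfg = paper_profile_config(seed=2)
        _cands, truth = generate_proteome(cfg)
        by_fam = {}
        for t in truth.genes.values():
            by_fam[t.subfamily] = by_fam.get(t.subfamily, 0) + 1
        assert by_fam == {"ZIK": 12, "MEKK": 22, "Raf": 44}
        assert len(truth.expressed_ids()) == 60
        # designated Raf ovule-preference splits
        hi0 = hi3 = 0
        for t in truth.genes.values():
            if t.subfamily != "Raf":
                continue
            e0, e3 = t.expression["ovule0"], t.expression["ovule3"]
            if e0 > 0 and e0 == 4.0 * e3:
                hi0 += 1
            if e3 > 0 and e3 == 4.0 * e0:
                hi3 += 1
        assert (hi0, hi3) == (11, 8)


class TestGenome:
    def test_gene_span_arithmetic(self, small_dataset):
        for t in small_dataset.truth.genes.values():
            span = t.annotation.end - t.annotation.start + 1
            assert span == sum(t.exon_lengths) + sum(t.intron_lengths)
            assert sum(t.exon_lengths) == 3 * len(t.protein)

    def test_cdna_is_exact_exon_concatenation(self, small_dataset):
        chrom = {c.id: c.sequence for c in small_dataset.chromosomes}
        cdna = {c.id: c.sequence for c in small_dataset.cdnas}
        for g, t in small_dataset.truth.genes.items():
            pieces = [chrom[t.chromosome][s - 1:e]
                      for s, e in t.annotation.exons]
            spliced = "".join(pieces)
            if t.strand == "-":
                spliced = revcomp(spliced)
            assert spliced == cdna[g], g

    def test_introns_start_gt_end_ag(self, small_dataset):
        chrom = {c.id: c.sequence for c in small_dataset.chromosomes}
        for g, t in small_dataset.truth.genes.items():
            exons = t.annotation.exons
            for (s0, e0), (s1, _) in zip(exons, exons[1:]):
                intron = chrom[t.chromosome][e0:s1 - 1]
                if t.strand == "-":
                    intron = revcomp(intron)
                assert intron.startswith("GT") and intron.endswith("AG"), g

    def test_reverse_translation_deterministic(self):
        assert reverse_translate("MKG") == reverse_translate("MKG")
        assert len(reverse_translate("MKG")) == 9

    def test_genes_do_not_overlap(self, small_dataset):
        by_chrom = {}
        for t in small_dataset.truth.genes.values():
            by_chrom.setdefault(t.chromosome, []).append(
                (t.annotation.start, t.annotation.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
                assert s1 > e0

    def test_tandem_partners_adjacent_same_chromosome(self, small_dataset):
        truth = small_dataset.truth
        for a, b in truth.duplication_pairs():
            ta, tb = truth.genes[a], truth.genes[b]
            if ta.tandem:
                assert ta.chromosome == tb.chromosome
            else:
                assert ta.chromosome != tb.chromosome


class TestReads:
    def test_realized_counts_sum_to_reads_per_sample(self, small_dataset):
        cfg = small_dataset.config
        for tissue, counts in small_dataset.realized_counts.items():
            assert sum(counts.values()) == cfg.reads_per_sample

    def test_silent_genes_receive_zero_reads(self, small_dataset):
        truth = small_dataset.truth
        for tissue, counts in small_dataset.realized_counts.items():
            for g, n in counts.items():
                if all(v == 0 for v in truth.genes[g].expression.values()):
                    assert n == 0

    def test_count_ratio_tracks_rpkm_times_length(self):
        """Two genes with equal planted RPKM but lengths L and 2L draw
        reads at ~1:2."""
        cfg = small_config(seed=21, duplication_pairs=0, tandem_pairs=0,
                           n_unexpressed=0, reads_per_sample=30000)
        ds = generate_dataset(cfg)
        lens = {c.id: len(c.sequence) for c in ds.cdnas}
        counts = ds.realized_counts["leaf"]
        expr = {g: t.expression["leaf"] for g, t in ds.truth.genes.items()}
        weights = {g: expr[g] * lens[g] for g in counts}
        total_w = sum(weights.values())
        for g, n in counts.items():
            expected = 30000 * weights[g] / total_w
            if expected >= 100:
                assert n == pytest.approx(expected, rel=0.25), g

    def test_fixed_seed_identical_fastq_bytes(self, tmp_path):
        cfg = small_config(seed=31)
        d1 = write_dataset(generate_dataset(cfg), tmp_path / "a")
        d2 = write_dataset(generate_dataset(cfg), tmp_path / "b")
        for tissue in ("leaf", "ovule0", "ovule3"):
            import gzip
            b1 = gzip.open(d1[f"reads_{tissue}"]).read()
            b2 = gzip.open(d2[f"reads_{tissue}"]).read()
            assert b1 == b2

    def test_read_length_longer_than_cdna_errors(self, small_dataset):
        cfg = small_config()
        cfg.read_length = 10**6
        with pytest.raises(GeneratorError, match="read_length"):
            simulate_reads(small_dataset.cdnas, small_dataset.truth, cfg)


class TestTruthSerialization:
    def test_json_roundtrip(self, small_dataset, tmp_path):
        p = tmp_path / "truth.json"
        small_dataset.truth.to_json(p)
        back = TruthTable.from_json(p)
        assert set(back.genes) == set(small_dataset.truth.genes)
        for g, t in small_dataset.truth.genes.items():
            b = back.genes[g]
            assert (b.protein, b.subfamily, b.exon_lengths,
                    b.expression) == (t.protein, t.subfamily,
                                      t.exon_lengths, t.expression)
            assert b.annotation == t.annotation
        assert back.decoy_ids == small_dataset.truth.decoy_ids
        assert back.realized_counts == small_dataset.truth.realized_counts
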
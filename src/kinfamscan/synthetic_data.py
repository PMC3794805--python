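"""Synthetic cotton-like benchmark generator with a full truth table.

The generator emulates the inputs of a genome-wide kinase-family survey
in a diploid plant: a proteome containing planted family members in three
subfamilies (ZIK / MEKK / Raf) plus decoys, a 13-chromosome genome
carrying the gene loci with exon/intron structure, the spliced cDNAs, and
three single-end tissue read sets (mature leaf, 0-DPA ovule, 3-DPA ovule)
realizing a planted expression table. Every planted property — subfamily,
locus, exon layout, duplication partner, per-tissue abundance — is
recorded in a :class:`TruthTable` so each pipeline stage can be scored.

Construction principles
-----------------------
* Family proteins are built around a kinase scaffold whose fixed motif
  islands satisfy the packaged hallmark patterns (a glycine-rich
  ATP-binding loop, an HRD catalytic loop, and a DFG core), plus exactly
  one subfamily signature realized from its consensus. Members derive
  from a per-subfamily ancestor by point mutation at ``mutation_rate``;
  planted motifs are never mutated. The kinase block sits N-terminally
  for ZIK members, C-terminally for Raf members and uniformly for MEKK.
* Decoys are either random non-kinase proteins or "near-miss" kinases:
  ancestor-derived sequences that pass the 50% identity screen but have
  a broken catalytic loop and no subfamily signature.
* Reverse translation uses one fixed codon per amino acid
  (``data/codons.yaml``) so protein -> CDS is reproducible.
* Introns begin GT and end AG; exon split points are placed so the cDNA
  base that follows each splice donor differs from the donor's first
  base, which makes the exact-match exon chain unique and exactly
  recoverable.
* Reads are error-free, single-end, sense-strand, drawn uniformly along
  each transcript with multiplicity proportional to truth RPKM x length.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .classify import SUBFAMILIES, classify_protein, compile_signatures
from .identify import load_hallmarks
from .seqio import (GeneAnnotation, SeqEntry, logger, revcomp, write_annotations,
                    write_fasta, write_fastq)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(_AA.encode(), dtype=np.uint8)
_NT_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

TISSUES = ("leaf", "ovule0", "ovule3")

# kinase scaffold islands (never mutated); spacers between them are
# ancestor-specific and mutable
_ATP_LOOP = "GEGSFGSV"
_VAIK = "AIK"
_HRD_LOOP = "HRDLKPEN"
_DFG = "DFG"

_MIN_EXON = 25
_SEED_LEN = 20

# protein length per subfamily (aa); Raf carries the long N-terminal
# regulatory region, ZIK the short one
_PROTEIN_LENGTH = {"ZIK": 450, "MEKK": 520, "Raf": 600}


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All dials of the synthetic dataset; defaults are the benchmark
    ("paper profile") conditions."""

    seed: int = 0
    n_zik: int = 12
    n_mekk: int = 22
    n_raf: int = 44
    n_decoys: int = 200
    near_miss_fraction: float = 0.25
    n_unexpressed: int = 18
    n_chromosomes: int = 13
    read_length: int = 50
    reads_per_sample: int = 30000
    exon_count_range: tuple[int, int] = (1, 23)
    intron_length_range: tuple[int, int] = (50, 300)
    spacer_range: tuple[int, int] = (3000, 8000)
    duplication_pairs: int = 12
    tandem_pairs: int = 2
    mutation_rate: float = 0.25
    duplication_divergence: float = 0.06
    expression: dict = field(default_factory=lambda: {
        "raf_higher_0dpa": 11, "raf_higher_3dpa": 8,
        "rpkm_range": [5.0, 500.0], "preference_ratio": 4.0,
        "tissue_dropout": 0.15,
    })

    def __post_init__(self) -> None:
        for name in ("n_zik", "n_mekk", "n_raf", "n_decoys", "n_unexpressed",
                     "reads_per_sample", "duplication_pairs", "tandem_pairs"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")
        if self.read_length < 20:
            raise GeneratorError("read_length must be >= 20 "
                                 "(signature-length constraint)")
        if not 0 <= self.mutation_rate < 1:
            raise GeneratorError("mutation_rate must be in [0,1)")
        self.exon_count_range = tuple(self.exon_count_range)
        self.intron_length_range = tuple(self.intron_length_range)
        self.spacer_range = tuple(self.spacer_range)
        if self.exon_count_range[0] < 1:
            raise GeneratorError("exon counts must be >= 1")
        if self.intron_length_range[0] < 2 + 2:
            raise GeneratorError("introns must fit GT..AG")
        if self.tandem_pairs > self.duplication_pairs:
            raise GeneratorError("tandem_pairs cannot exceed duplication_pairs")

    @property
    def n_family(self) -> int:
        return self.n_zik + self.n_mekk + self.n_raf

    @property
    def subfamily_counts(self) -> dict[str, int]:
        return {"ZIK": self.n_zik, "MEKK": self.n_mekk, "Raf": self.n_raf}


def paper_profile_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The packaged benchmark profile with the given seed."""
    text = resources.files("kinfamscan.data").joinpath("paper_profile.yaml").read_text()
    raw = yaml.safe_load(text)
    raw.update(overrides)
    return GeneratorConfig(seed=seed, **raw)


def config_from_dict(raw: dict) -> GeneratorConfig:
    return GeneratorConfig(**raw)


@dataclass
class GeneTruth:
    """Planted ground truth for one family gene."""

    gene_id: str
    subfamily: str
    protein: str
    signature: str
    domain_span: tuple[int, int]  # 0-based half-open, in the protein
    duplication_partner: str | None = None
    tandem: bool = False
    chromosome: str | None = None
    strand: str | None = None
    locus_start: int | None = None  # 1-based
    exon_lengths: list[int] = field(default_factory=list)   # transcript order
    intron_lengths: list[int] = field(default_factory=list)  # transcript order
    expression: dict[str, float] = field(default_factory=dict)
    annotation: GeneAnnotation | None = None


@dataclass
class TruthTable:
    """Generator-side ground truth against which every stage is scored."""

    genes: dict[str, GeneTruth]
    decoy_ids: list[str]
    near_miss_ids: list[str]
    queries: list[SeqEntry]
    realized_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def family_ids(self) -> list[str]:
        return list(self.genes)

    def subfamily_of(self) -> dict[str, str]:
        return {g: t.subfamily for g, t in self.genes.items()}

    def expressed_ids(self) -> list[str]:
        return [g for g, t in self.genes.items()
                if any(v > 0 for v in t.expression.values())]

    def duplication_pairs(self) -> list[tuple[str, str]]:
        pairs = set()
        for g, t in self.genes.items():
            if t.duplication_partner:
                pairs.add(tuple(sorted((g, t.duplication_partner))))
        return sorted(pairs)

    def validate(self) -> None:
        for g, t in self.genes.items():
            if t.duplication_partner:
                partner = self.genes[t.duplication_partner]
                if partner.duplication_partner != g:
                    raise GeneratorError(f"asymmetric duplication partner {g}")
            if any(v < 0 for v in t.expression.values()):
                raise GeneratorError(f"negative expression for {g}")

    def to_json(self, path: str | Path) -> None:
        def encode(obj):
            if isinstance(obj, GeneAnnotation):
                return dataclasses.asdict(obj)
            if isinstance(obj, SeqEntry):
                return dataclasses.asdict(obj)
            return obj
        payload = {
            "genes": {g: encode_gene(t) for g, t in self.genes.items()},
            "decoy_ids": self.decoy_ids,
            "near_miss_ids": self.near_miss_ids,
            "queries": [dataclasses.asdict(q) for q in self.queries],
            "realized_counts": self.realized_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        raw = json.loads(Path(path).read_text())
        genes = {}
        for g, t in raw["genes"].items():
            ann = t.pop("annotation")
            gt = GeneTruth(**{**t,
                              "domain_span": tuple(t["domain_span"]),
                              "annotation": None})
            if ann is not None:
                gt.annotation = GeneAnnotation(
                    ann["gene_id"], ann["chromosome"], ann["start"], ann["end"],
                    ann["strand"], [tuple(e) for e in ann["exons"]])
            genes[g] = gt
        return cls(genes=genes, decoy_ids=raw["decoy_ids"],
                   near_miss_ids=raw["near_miss_ids"],
                   queries=[SeqEntry(**q) for q in raw["queries"]],
                   realized_counts=raw.get("realized_counts", {}))


def encode_gene(t: GeneTruth) -> dict:
    d = dataclasses.asdict(t)
    if t.annotation is not None:
        d["annotation"] = dataclasses.asdict(t.annotation)
    return d


# ---------------------------------------------------------------- sequences

def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return _AA_ARR[rng.integers(0, len(_AA), n)].tobytes().decode()

def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return _NT_ARR[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate each position with probability ``rate`` to a random
    different residue."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        repl = _AA_ARR[rng.integers(0, len(_AA), n_hit)]
        same = repl == arr[hit]
        while same.any():
            repl[same] = _AA_ARR[rng.integers(0, len(_AA), int(same.sum()))]
            same = repl == arr[hit]
        arr[hit] = repl
    return arr.tobytes().decode()


def _realize_signature(subfamily: str, rng: np.random.Generator,
                       mekk_pattern, strict: bool = True) -> str:
    """One realization of the subfamily signature consensus. Raf
    realizations are resampled until they do not satisfy the
    higher-precedence MEKK consensus."""
    pick = lambda s: s[rng.integers(0, len(s))]
    if subfamily == "ZIK":
        return "GTPEFMAPELY"
    if subfamily == "MEKK":
        return "G" + pick("TS") + "P" + pick(_AA) + pick("WF") + "MAPEV"
    while True:
        sig = "GT" + pick(_AA) + pick(_AA) + pick("WY") + "MAPE" + pick("LV")
        if not strict or not mekk_pattern.matches(sig):
            return sig


@dataclass
class _Ancestor:
    subfamily: str
    flank: str             # residue pool outside the kinase block
    spacers: tuple[str, ...]  # mutable spacers inside the block


def _make_ancestor(subfamily: str, rng: np.random.Generator) -> _Ancestor:
    length = _PROTEIN_LENGTH[subfamily]
    spacers = (_rand_protein(rng, 8), _rand_protein(rng, 10),
               _rand_protein(rng, 8), _rand_protein(rng, 4),
               _rand_protein(rng, 15))
    block_len = (len(_ATP_LOOP) + len(_VAIK) + len(_HRD_LOOP) + len(_DFG)
                 + 11 + sum(len(s) for s in spacers))
    flank_len = length - block_len
    if flank_len < 60:
        raise GeneratorError(
            f"protein length {length} too short for the kinase scaffold")
    return _Ancestor(subfamily, _rand_protein(rng, flank_len), spacers)


def _assemble(flank: str, spacers: tuple[str, ...], signature: str,
              offset: int) -> tuple[str, tuple[int, int]]:
    """Insert the kinase block into the flank at ``offset``; returns the
    sequence and the hallmark-anchored domain span (0-based half-open)."""
    s8a, s10, s8b, s4, s15 = spacers
    block = (_ATP_LOOP + s8a + _VAIK + s10 + _HRD_LOOP + s8b + _DFG
             + s4 + signature + s15)
    seq = flank[:offset] + block + flank[offset:]
    span = (offset, offset + len(block) - len(s15))
    return seq, span


def _block_offset(subfamily: str, flank_len: int,
                  rng: np.random.Generator) -> int:
    if subfamily == "ZIK":
        return min(30, flank_len)
    if subfamily == "Raf":
        return max(0, flank_len - 30)
    return int(rng.integers(0, flank_len + 1))


def generate_proteome(config: GeneratorConfig
                      ) -> tuple[list[SeqEntry], TruthTable]:
    """Planted family proteins + decoys, with the query set and truth.

    Deterministic for a fixed config. The candidate list is shuffled so
    family members and decoys are interleaved as in a real database.
    """
    rng = np.random.default_rng([config.seed, 1])
    signatures = compile_signatures()
    hallmarks = load_hallmarks()
    required = {p.name for p in hallmarks}

    ancestors = {fam: _make_ancestor(fam, rng) for fam in SUBFAMILIES}

    # gene ids in subfamily blocks: ZIK, then MEKK, then Raf
    gene_ids: list[str] = []
    subfam_of: dict[str, str] = {}
    for fam in SUBFAMILIES:
        for _ in range(config.subfamily_counts[fam]):
            gid = f"fam{len(gene_ids) + 1:03d}"
            gene_ids.append(gid)
            subfam_of[gid] = fam

    pairs = _choose_duplication_pairs(config, gene_ids, subfam_of, rng)
    partner_of = {}
    tandem_ids = set()
    for k, (a, b) in enumerate(pairs):
        partner_of[a], partner_of[b] = b, a
        if k < config.tandem_pairs:
            tandem_ids.update((a, b))

    def build_member(fam: str, derive_from: str | None,
                     genes: dict[str, GeneTruth]) -> tuple[str, str, tuple[int, int]]:
        anc = ancestors[fam]
        for _ in range(40):
            if derive_from is None:
                flank = _mutate(anc.flank, config.mutation_rate, rng)
                spacers = tuple(_mutate(s, config.mutation_rate, rng)
                                for s in anc.spacers)
                offset = _block_offset(fam, len(flank), rng)
            else:
                src = genes[derive_from]
                flank, spacers, offset = src._parts  # set below
                flank = _mutate(flank, config.duplication_divergence, rng)
                spacers = tuple(_mutate(s, config.duplication_divergence, rng)
                                for s in spacers)
            sig = _realize_signature(fam, rng, signatures["MEKK"])
            seq, span = _assemble(flank, spacers, sig, offset)
            call = classify_protein(SeqEntry("tmp", "", seq), span, signatures)
            ok_hallmarks = {p.name for p in hallmarks
                           if p.matches(seq)} == required
            if call.subfamily == fam and ok_hallmarks:
                return seq, sig, span, (flank, spacers, offset)
        raise GeneratorError(f"could not realize a valid {fam} member")

    genes: dict[str, GeneTruth] = {}
    # ancestors' own members first so partners can derive from them
    for gid in gene_ids:
        fam = subfam_of[gid]
        partner = partner_of.get(gid)
        derive = partner if (partner is not None and partner in genes) else None
        seq, sig, span, parts = build_member(fam, derive, genes)
        t = GeneTruth(gene_id=gid, subfamily=fam, protein=seq, signature=sig,
                      domain_span=span, duplication_partner=partner,
                      tandem=gid in tandem_ids)
        t._parts = parts  # transient, for partner derivation
        genes[gid] = t
    for t in genes.values():
        del t._parts

    # decoys: near-miss kinases (pass the identity screen, fail hallmark
    # validation) and random non-kinase proteins
    n_near = int(round(config.n_decoys * config.near_miss_fraction))
    decoy_entries: list[SeqEntry] = []
    near_ids: list[str] = []
    for k in range(config.n_decoys):
        did = f"decoy{k + 1:03d}"
        if k < n_near:
            # ZIK/Raf scaffolds have fixed domain placement, so a
            # near-miss is guaranteed to clear the identity screen
            fam = ("ZIK", "Raf")[int(rng.integers(0, 2))]
            anc = ancestors[fam]
            for _ in range(40):
                flank = _mutate(anc.flank, config.mutation_rate, rng)
                spacers = tuple(_mutate(s, config.mutation_rate, rng)
                                for s in anc.spacers)
                broken = "HR" + "".join(
                    c for c in _rand_protein(rng, len(_HRD_LOOP) - 2))
                block = (_ATP_LOOP + spacers[0] + _VAIK + spacers[1] + broken
                         + spacers[2] + _DFG + spacers[3]
                         + _rand_protein(rng, 11) + spacers[4])
                offset = _block_offset(fam, len(flank), rng)
                seq = flank[:offset] + block + flank[offset:]
                matched = {p.name for p in hallmarks if p.matches(seq)}
                if matched != required:
                    break
            near_ids.append(did)
        else:
            for _ in range(40):
                seq = _rand_protein(rng, int(rng.integers(300, 901)))
                matched = {p.name for p in hallmarks if p.matches(seq)}
                if matched != required:
                    break
        decoy_entries.append(SeqEntry(did, "decoy", seq))

    # query set: undiverged ancestors, with the MEKK ancestor realized at
    # three domain placements (as a multi-species query collection samples
    # the placement variability of that subfamily)
    queries = []
    for fam in SUBFAMILIES:
        anc = ancestors[fam]
        if fam == "MEKK":
            offsets = [0, len(anc.flank) // 2, len(anc.flank)]
        else:
            offsets = [_block_offset(fam, len(anc.flank), rng)]
        for k, offset in enumerate(offsets, 1):
            sig = _realize_signature(fam, rng, signatures["MEKK"])
            seq, _ = _assemble(anc.flank, anc.spacers, sig, offset)
            queries.append(SeqEntry(f"query_{fam}_{k}",
                                    f"{fam} subfamily query", seq))

    candidates = [SeqEntry(g, f"{genes[g].subfamily} family member",
                           genes[g].protein) for g in gene_ids] + decoy_entries
    order = rng.permutation(len(candidates))
    candidates = [candidates[i] for i in order]

    truth = TruthTable(genes=genes,
                       decoy_ids=[e.id for e in decoy_entries],
                       near_miss_ids=near_ids, queries=queries)
    _plant_expression(truth, config, rng)
    truth.validate()
    logger.info("generate_proteome: %d family + %d decoys",
                len(genes), len(decoy_entries))
    return candidates, truth


def _choose_duplication_pairs(config: GeneratorConfig, gene_ids: list[str],
                              subfam_of: dict[str, str],
                              rng: np.random.Generator
                              ) -> list[tuple[str, str]]:
    """Pair quota per subfamily (Raf-heavy, mirroring the benchmark),
    partners drawn without replacement inside each subfamily."""
    by_fam = {fam: [g for g in gene_ids if subfam_of[g] == fam]
              for fam in SUBFAMILIES}
    capacity = {fam: len(v) // 2 for fam, v in by_fam.items()}
    if config.duplication_pairs > sum(capacity.values()):
        raise GeneratorError("duplication_pairs exceeds family capacity")
    quota = {"ZIK": 0, "MEKK": 0, "Raf": 0}
    remaining = config.duplication_pairs
    if config.duplication_pairs == 12 and capacity["ZIK"] >= 2 \
            and capacity["MEKK"] >= 2 and capacity["Raf"] >= 8:
        quota = {"ZIK": 2, "MEKK": 2, "Raf": 8}
    else:
        for fam in ("Raf", "MEKK", "ZIK"):
            take = min(remaining, capacity[fam])
            quota[fam] = take
            remaining -= take
    pairs: list[tuple[str, str]] = []
    # tandem pairs are taken from Raf first (listed first below)
    for fam in ("Raf", "MEKK", "ZIK"):
        members = by_fam[fam]
        picked = rng.permutation(len(members))
        for k in range(quota[fam]):
            a = members[picked[2 * k]]
            b = members[picked[2 * k + 1]]
            pairs.append(tuple(sorted((a, b))))
    return pairs


def _plant_expression(truth: TruthTable, config: GeneratorConfig,
                      rng: np.random.Generator) -> None:
    """Per-gene, per-tissue truth RPKM implementing the configured
    expression classes: exactly n_unexpressed silent genes, and the
    designated Raf ovule-preference splits."""
    expr_cfg = config.expression
    lo, hi = expr_cfg.get("rpkm_range", [5.0, 500.0])
    ratio = expr_cfg.get("preference_ratio", 4.0)
    dropout = expr_cfg.get("tissue_dropout", 0.15)
    raf_ids = [g for g, t in truth.genes.items() if t.subfamily == "Raf"]
    n_hi0 = expr_cfg.get("raf_higher_0dpa", 0)
    n_hi3 = expr_cfg.get("raf_higher_3dpa", 0)
    if n_hi0 + n_hi3 > len(raf_ids):
        raise GeneratorError("Raf preference counts exceed Raf gene count")
    hi0 = raf_ids[:n_hi0]
    hi3 = raf_ids[n_hi0:n_hi0 + n_hi3]
    designated = set(hi0) | set(hi3)
    undesignated = [g for g in truth.genes if g not in designated]
    if config.n_unexpressed > len(undesignated):
        raise GeneratorError("n_unexpressed exceeds undesignated gene count")
    silent = set(rng.choice(undesignated, size=config.n_unexpressed,
                            replace=False)) if config.n_unexpressed else set()

    def draw() -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for gid, t in truth.genes.items():
        if gid in silent:
            t.expression = {tis: 0.0 for tis in TISSUES}
        elif gid in hi0:
            v = draw()
            t.expression = {"leaf": draw(), "ovule0": v, "ovule3": v / ratio}
        elif gid in hi3:
            v = draw()
            t.expression = {"leaf": draw(), "ovule0": v / ratio, "ovule3": v}
        else:
            while True:
                vals = {tis: (0.0 if rng.random() < dropout else draw())
                        for tis in TISSUES}
                if any(v > 0 for v in vals.values()):
                    break
            t.expression = vals


# ------------------------------------------------------------------ genome

def load_codon_table() -> dict[str, str]:
    text = resources.files("kinfamscan.data").joinpath("codons.yaml").read_text()
    return yaml.safe_load(text)["codons"]


def reverse_translate(protein: str, codons: dict[str, str] | None = None) -> str:
    codons = codons or load_codon_table()
    return "".join(codons[aa] for aa in protein)


def _split_exons(cds: str, k: int, rng: np.random.Generator) -> list[int]:
    """Exon lengths (transcript order) for a k-exon layout of ``cds``.

    Split points keep every exon >= 25 nt and are nudged so the cDNA base
    that starts each downstream exon is not 'G' (the splice-donor first
    base), making the exact-match chain unique.
    """
    L = len(cds)
    if k * _MIN_EXON > L:
        raise GeneratorError(f"cannot split {L} nt into {k} exons")
    if k == 1:
        return [L]
    cuts = []
    for i in range(1, k):
        base = round(i * L / k)
        jitter = int(rng.integers(-10, 11))
        cuts.append(base + jitter)
    cuts = sorted(cuts)
    # enforce spacing, then dodge 'G' starts
    adjusted: list[int] = []
    prev = 0
    for i, c in enumerate(cuts):
        lo = prev + _MIN_EXON
        hi = L - (k - 1 - i) * _MIN_EXON
        c = min(max(c, lo), hi)
        placed = None
        for delta in range(0, 13):
            for cand in ((c + delta, c - delta) if delta else (c,)):
                if lo <= cand <= hi and cds[cand] != "G":
                    placed = cand
                    break
            if placed is not None:
                break
        if placed is None:
            raise GeneratorError("no valid exon split point found")
        adjusted.append(placed)
        prev = placed
    bounds = [0] + adjusted + [L]
    return [bounds[i + 1] - bounds[i] for i in range(k)]


def _exon_counts(truth: TruthTable, config: GeneratorConfig,
                 rng: np.random.Generator) -> dict[str, int]:
    """Per-gene exon counts. Under the benchmark profile the layout
    mirrors the published family: ZIK genes have 2/7/8 exons with the
    duplication pairs sharing counts, MEKK contributes the single-exon
    and 23-exon extremes, Raf spans 3..17."""
    lo, hi = config.exon_count_range
    by_fam = {fam: [g for g, t in truth.genes.items() if t.subfamily == fam]
              for fam in SUBFAMILIES}
    counts: dict[str, int] = {}
    paper = (config.subfamily_counts == {"ZIK": 12, "MEKK": 22, "Raf": 44}
             and (lo, hi) == (1, 23))
    if paper:
        zik_counts = [8, 2, 7, 7, 7, 8, 7, 7, 2, 7, 7, 7]
        for g, c in zip(by_fam["ZIK"], zik_counts):
            counts[g] = c
        mekk = by_fam["MEKK"]
        fixed = [1, 1, 1, 1, 23, 23]
        for g, c in zip(mekk, fixed):
            counts[g] = c
        for g in mekk[len(fixed):]:
            counts[g] = int(rng.integers(2, 17))
        for g in by_fam["Raf"]:
            counts[g] = int(rng.integers(3, 18))
    else:
        gids = list(truth.genes)
        for g in gids:
            cap = len(truth.genes[g].protein) * 3 // _MIN_EXON
            counts[g] = int(min(rng.integers(lo, hi + 1), cap))
        if gids:
            counts[gids[0]] = lo
            longest = max(gids, key=lambda g: len(truth.genes[g].protein))
            counts[longest] = min(hi, len(truth.genes[longest].protein) * 3
                                  // _MIN_EXON)
    # duplication partners share their exon count (conserved structure)
    for a, b in truth.duplication_pairs():
        counts[b] = counts[a]
    return counts


def _chromosome_slots(config: GeneratorConfig) -> dict[int, dict[str, int]]:
    """Subfamily slots per chromosome.

    Benchmark profile: chromosome 6 carries 11 genes, chromosome 10
    three; ZIK and MEKK are restricted to 10 of the 13 chromosomes
    (absent from 1, 9 and 10); Raf is present everywhere. Otherwise
    genes are distributed round-robin.
    """
    n_chrom = config.n_chromosomes
    slots = {c: {"ZIK": 0, "MEKK": 0, "Raf": 0} for c in range(1, n_chrom + 1)}
    paper = (config.subfamily_counts == {"ZIK": 12, "MEKK": 22, "Raf": 44}
             and n_chrom == 13)
    if paper:
        zik = {2: 2, 3: 2, 4: 1, 5: 1, 6: 1, 7: 1, 8: 1, 11: 1, 12: 1, 13: 1}
        mekk = {2: 2, 3: 2, 4: 3, 5: 3, 6: 2, 7: 2, 8: 2, 11: 2, 12: 2, 13: 2}
        raf = {1: 6, 2: 2, 3: 2, 4: 2, 5: 2, 6: 8, 7: 3, 8: 3, 9: 6, 10: 3,
               11: 3, 12: 2, 13: 2}
        for c in slots:
            slots[c] = {"ZIK": zik.get(c, 0), "MEKK": mekk.get(c, 0),
                        "Raf": raf.get(c, 0)}
    else:
        # generic profile: chromosomes hold any subfamily, genes spread
        # as evenly as possible
        slots = {c: {"ANY": 0} for c in range(1, n_chrom + 1)}
        c = 1
        for _ in range(config.n_family):
            slots[c]["ANY"] += 1
            c = c % n_chrom + 1
    return slots


def _assign_chromosomes(truth: TruthTable, config: GeneratorConfig
                        ) -> dict[int, list[str]]:
    """Fill chromosome slots; tandem partners land adjacently on one
    chromosome, dispersed partners on different chromosomes."""
    slots = _chromosome_slots(config)
    generic = "ANY" in next(iter(slots.values()))
    free = {c: dict(s) for c, s in slots.items()}
    placement: dict[int, list[str]] = {c: [] for c in free}
    placed: set[str] = set()

    def slot_key(fam: str) -> str:
        return "ANY" if generic else fam

    def take(c: int, fam: str, gid: str) -> None:
        free[c][slot_key(fam)] -= 1
        placement[c].append(gid)
        placed.add(gid)

    for a, b in truth.duplication_pairs():
        fam = truth.genes[a].subfamily
        if truth.genes[a].tandem:
            c = next((c for c in free if free[c][slot_key(fam)] >= 2), None)
            if c is None:
                raise GeneratorError("no chromosome with room for tandem pair")
            take(c, fam, a)
            take(c, fam, b)
        else:
            ca = next((c for c in free if free[c][slot_key(fam)] >= 1), None)
            cb = next((c for c in free if c != ca and free[c][slot_key(fam)] >= 1), None)
            if ca is None or cb is None:
                raise GeneratorError("no chromosomes for dispersed pair")
            take(ca, fam, a)
            take(cb, fam, b)
    for gid, t in truth.genes.items():
        if gid in placed:
            continue
        c = next((c for c in free if free[c][slot_key(t.subfamily)] >= 1), None)
        if c is None:
            raise GeneratorError("chromosome slots exhausted")
        take(c, t.subfamily, gid)
    return placement


def generate_genome(truth: TruthTable, config: GeneratorConfig
                    ) -> tuple[list[SeqEntry], list[GeneAnnotation], list[SeqEntry]]:
    """Multi-chromosome genome, gene annotations and spliced cDNAs.

    Each gene's CDS (deterministic reverse translation of its protein) is
    split into the truth exon layout, separated by random GT..AG introns,
    and placed without overlap; the cDNA is the exact exon concatenation.
    Minus-strand genes are inserted reverse-complemented.
    """
    rng = np.random.default_rng([config.seed, 2])
    codons = load_codon_table()
    counts = _exon_counts(truth, config, rng)
    placement = _assign_chromosomes(truth, config)
    ilo, ihi = config.intron_length_range
    slo, shi = config.spacer_range

    chromosomes: list[SeqEntry] = []
    annotations: list[GeneAnnotation] = []
    cdnas: list[SeqEntry] = []

    for c in sorted(placement):
        name = f"chr{c:02d}"
        parts: list[str] = []
        pos = 0
        for gid in placement[c]:
            t = truth.genes[gid]
            cds = reverse_translate(t.protein, codons)
            exon_lengths = _split_exons(cds, counts[gid], rng)
            intron_lengths = [int(rng.integers(ilo, ihi + 1))
                              for _ in range(len(exon_lengths) - 1)]
            spacer = _rand_dna(rng, int(rng.integers(slo, shi + 1)))
            parts.append(spacer)
            pos += len(spacer)

            gene_parts: list[str] = []
            exon_local: list[tuple[int, int]] = []  # 0-based half-open
            cursor = 0
            off = 0
            for i, elen in enumerate(exon_lengths):
                exon_seq = cds[cursor:cursor + elen]
                exon_local.append((off, off + elen))
                gene_parts.append(exon_seq)
                cursor += elen
                off += elen
                if i < len(intron_lengths):
                    ilen = intron_lengths[i]
                    gene_parts.append("GT" + _rand_dna(rng, ilen - 4) + "AG")
                    off += ilen
            gene_seq = "".join(gene_parts)
            Lg = len(gene_seq)
            strand = "+" if rng.random() < 0.5 else "-"
            fwd = gene_seq if strand == "+" else revcomp(gene_seq)
            if strand == "+":
                exons = [(pos + s + 1, pos + e) for s, e in exon_local]
            else:
                exons = [(pos + Lg - e + 1, pos + Lg - s) for s, e in exon_local]
                exons = sorted(exons)
            ann = GeneAnnotation(gid, name, pos + 1, pos + Lg, strand, exons)
            annotations.append(ann)
            t.chromosome = name
            t.strand = strand
            t.locus_start = pos + 1
            t.exon_lengths = exon_lengths
            t.intron_lengths = intron_lengths
            t.annotation = ann
            cdnas.append(SeqEntry(gid, f"{t.subfamily} cDNA", cds))
            parts.append(fwd)
            pos += Lg
        parts.append(_rand_dna(rng, int(rng.integers(slo, shi + 1))))
        chromosomes.append(SeqEntry(name, "", "".join(parts)))

    annotations.sort(key=lambda a: (a.chromosome, a.start))
    cdnas.sort(key=lambda e: e.id)
    logger.info("generate_genome: %d genes on %d chromosomes",
                len(annotations), len(chromosomes))
    return chromosomes, annotations, cdnas


# ------------------------------------------------------------------- reads

def simulate_reads(cdnas: list[SeqEntry], truth: TruthTable,
                   config: GeneratorConfig
                   ) -> tuple[dict[str, list[SeqEntry]], dict[str, dict[str, int]]]:
    """Three tissue read sets realizing the planted expression table.

    Per tissue, ``reads_per_sample`` error-free sense-strand reads are
    drawn with per-transcript multiplicity proportional to truth RPKM x
    transcript length and uniform start positions. Genes silent in the
    truth receive zero reads. Returns the reads and the realized
    per-transcript count table (which sums to reads_per_sample).
    """
    rng = np.random.default_rng([config.seed, 3])
    rl = config.read_length
    seqs = {e.id: e.sequence for e in cdnas}
    short = [g for g, s in seqs.items() if len(s) < rl]
    if short:
        raise GeneratorError(f"read_length {rl} exceeds cDNA length of {short[:3]}")
    gids = sorted(seqs)
    reads: dict[str, list[SeqEntry]] = {}
    realized: dict[str, dict[str, int]] = {}
    for tissue in TISSUES:
        weights = np.array([truth.genes[g].expression.get(tissue, 0.0)
                            * len(seqs[g]) for g in gids])
        total = weights.sum()
        tissue_reads: list[SeqEntry] = []
        if total <= 0 or config.reads_per_sample == 0:
            counts = np.zeros(len(gids), dtype=int)
        else:
            counts = rng.multinomial(config.reads_per_sample, weights / total)
        r = 0
        for g, n in zip(gids, counts):
            seq = seqs[g]
            starts = rng.integers(0, len(seq) - rl + 1, size=int(n))
            for s in np.sort(starts):
                tissue_reads.append(
                    SeqEntry(f"{tissue}_{r:06d}", f"src={g}",
                             seq[int(s):int(s) + rl]))
                r += 1
        reads[tissue] = tissue_reads
        realized[tissue] = {g: int(n) for g, n in zip(gids, counts)}
    truth.realized_counts = realized
    logger.info("simulate_reads: %s",
                {t: len(v) for t, v in reads.items()})
    return reads, realized


# ------------------------------------------------------------------ bundle

@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    candidates: list[SeqEntry]
    truth: TruthTable
    chromosomes: list[SeqEntry]
    annotations: list[GeneAnnotation]
    cdnas: list[SeqEntry]
    reads: dict[str, list[SeqEntry]]
    realized_counts: dict[str, dict[str, int]]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Run the full generator: proteome -> genome -> reads."""
    candidates, truth = generate_proteome(config)
    chromosomes, annotations, cdnas = generate_genome(truth, config)
    reads, realized = simulate_reads(cdnas, truth, config)
    return SyntheticDataset(config, candidates, truth, chromosomes,
                            annotations, cdnas, reads, realized)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "queries": outdir / "queries.fasta",
        "genome": outdir / "genome.fasta",
        "cdna": outdir / "cdna.fasta",
        "annotations": outdir / "annotations.gff.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.candidates, paths["proteome"])
    write_fasta(ds.truth.queries, paths["queries"])
    write_fasta(ds.chromosomes, paths["genome"])
    write_fasta(ds.cdnas, paths["cdna"])
    write_annotations(ds.annotations, paths["annotations"])
    ds.truth.to_json(paths["truth"])
    for tissue, rs in ds.reads.items():
        p = outdir / f"reads_{tissue}.fastq.gz"
        write_fastq(rs, p)
        paths[f"reads_{tissue}"] = p
    return paths
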
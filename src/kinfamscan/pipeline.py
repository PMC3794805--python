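"""End-to-end orchestration: simulate -> identify -> classify ->
protparam -> structure -> tree -> duplication -> expression, with a
summary report and truth-table scoring.

Every stage writes its output files into the run directory so a run can
be resumed or inspected stage by stage; the summary is written both as
JSON and as readable text. Given a fixed seed the whole run is
deterministic, byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import classify as _classify
from . import duplication as _duplication
from . import expression as _expression
from . import genestruct as _genestruct
from . import phylogeny as _phylogeny
from . import protparam as _protparam
from .identify import load_hallmarks, run_identification
from .seqio import SeqEntry, logger, write_fasta, write_tsv
from .synthetic_data import (GeneratorConfig, SyntheticDataset,
                             generate_dataset, write_dataset)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage}: {cause}")


@dataclass
class PipelineConfig:
    """Every numeric setting of the pipeline in one place."""

    seed: int = 0
    outdir: str | Path = "kinfamscan_run"
    generator: GeneratorConfig | None = None
    identity_threshold: float = 0.50
    redundancy_identity: float = 0.98
    redundancy_coverage: float = 0.98
    duplication_coverage: float = 0.8
    duplication_identity: float = 0.8
    linkage_window: int = 25_000
    bootstrap_replicates: int = 1000
    min_read_length: int = 20
    run_tree: bool = True
    run_bootstrap: bool = False

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "redundancy_identity",
                     "redundancy_coverage", "duplication_coverage",
                     "duplication_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise PipelineError("config", f"{name} must be in (0,1]")
        if self.bootstrap_replicates < 1:
            raise PipelineError("config", "bootstrap_replicates must be >= 1")
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        else:
            self.generator.seed = self.seed


@dataclass
class SummaryReport:
    """Headline numbers of one pipeline run."""

    n_candidates: int = 0
    n_identity_passed: int = 0
    n_nonredundant: int = 0
    n_accepted: int = 0
    subfamily_counts: dict = field(default_factory=dict)
    chromosome_counts: dict = field(default_factory=dict)
    n_duplication_pairs: int = 0
    n_duplication_events: int = 0
    n_expressed: int = 0
    expression_preferences: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)

    def check(self) -> None:
        funnel = (self.n_candidates, self.n_identity_passed,
                  self.n_nonredundant, self.n_accepted)
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise PipelineError("report", "funnel counts must be "
                                "monotonically non-increasing")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            "kinfamscan pipeline summary",
            f"  candidates screened       {self.n_candidates}",
            f"  passed identity screen    {self.n_identity_passed}",
            f"  non-redundant             {self.n_nonredundant}",
            f"  accepted family members   {self.n_accepted}",
            f"  subfamilies               {self.subfamily_counts}",
            f"  genes per chromosome      {self.chromosome_counts}",
            f"  duplication pairs/events  {self.n_duplication_pairs}"
            f"/{self.n_duplication_events}",
            f"  expressed genes           {self.n_expressed}",
            f"  ovule preferences         {self.expression_preferences}",
        ]
        if self.recovery:
            lines.append(f"  truth recovery            {self.recovery}")
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> tuple[SummaryReport, dict]:
    """Run every stage on a freshly simulated dataset.

    Returns the summary report and a dict of in-memory stage outputs
    (dataset, accepted entries, calls, chains, pairs, records, tree).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    def stage(name: str, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    ds: SyntheticDataset = stage(
        "simulate", lambda: generate_dataset(config.generator))
    stage("simulate", lambda: write_dataset(ds, outdir / "data"))
    outputs["dataset"] = ds

    hallmarks = load_hallmarks()
    accepted, reports = stage("identify", lambda: run_identification(
        ds.candidates, ds.truth.queries, hallmarks,
        config.identity_threshold, config.redundancy_identity,
        config.redundancy_coverage))
    outputs["accepted"], outputs["reports"] = accepted, reports
    write_tsv([dataclasses.asdict(r) | {
        "matched_hallmarks": ",".join(sorted(r.matched_hallmarks))}
        for r in reports], outdir / "identify.tsv",
        ["protein_id", "best_query_id", "best_identity", "passed_identity",
         "matched_hallmarks", "accepted", "redundant_with"])
    write_fasta(accepted, outdir / "accepted.fasta")

    calls = stage("classify", lambda: _classify.classify_all(accepted, hallmarks))
    outputs["calls"] = calls
    subfam_counts = _classify.summarize_subfamilies(calls)
    write_tsv([{
        "protein_id": c.protein_id, "subfamily": c.subfamily,
        "signature": c.signature_hit[0] if c.signature_hit else "",
        "position": c.signature_hit[1] if c.signature_hit else "",
        "domain_position": c.domain_position, "ambiguous": c.ambiguous}
        for c in calls], outdir / "classify.tsv",
        ["protein_id", "subfamily", "signature", "position",
         "domain_position", "ambiguous"])

    params = stage("protparam", lambda: _protparam.protein_parameters(accepted))
    outputs["params"] = params
    write_tsv(params, outdir / "protparam.tsv", ["id", "AA", "pI", "Mw_kDa"])

    accepted_ids = {e.id for e in accepted}
    cdnas = [c for c in ds.cdnas if c.id in accepted_ids]
    chains, failures = stage("structure", lambda: _genestruct.gene_structures(
        cdnas, ds.chromosomes))
    outputs["chains"], outputs["structure_failures"] = chains, failures
    subfam_of = {c.protein_id: c.subfamily for c in calls}
    chrom_counts, _presence = _genestruct.chromosome_distribution(
        chains, subfam_of)
    write_tsv([{
        "gene_id": c.gene_id, "subfamily": subfam_of.get(c.gene_id, ""),
        "chromosome": c.chromosome, "strand": c.strand,
        "exon_count": c.exon_count,
        "intron_lengths": ",".join(map(str, c.intron_lengths))}
        for c in chains], outdir / "structure.tsv",
        ["gene_id", "subfamily", "chromosome", "strand", "exon_count",
         "intron_lengths"])

    tree = None
    if config.run_tree:
        def build_tree():
            msa = _phylogeny.progressive_msa(accepted)
            if config.run_bootstrap and len(accepted) >= 4:
                return _phylogeny.bootstrap_support(
                    msa, config.bootstrap_replicates, config.seed)
            return _phylogeny.neighbor_joining(_phylogeny.p_distance(msa))
        tree = stage("tree", build_tree)
        outputs["tree"] = tree
        (outdir / "tree.nwk").write_text(
            tree.newick(with_support=config.run_bootstrap) + "\n")

    pairs, n_events = stage("duplication", lambda: _duplication.call_duplications(
        cdnas, chains, config.duplication_coverage,
        config.duplication_identity, config.linkage_window))
    outputs["pairs"], outputs["n_events"] = pairs, n_events
    write_tsv([dataclasses.asdict(p) for p in pairs], outdir / "duplication.tsv",
              ["gene_a", "gene_b", "coverage_longer", "identity", "linkage",
               "event_id"])

    records = stage("express", lambda: _expression.quantify(
        cdnas, ds.reads, config.min_read_length))
    expr_calls = stage("express", lambda: _expression.call_expression(records))
    outputs["records"], outputs["expression_calls"] = records, expr_calls
    write_tsv([dataclasses.asdict(r) for r in records], outdir / "rpkm.tsv",
              ["transcript_id", "tissue", "C", "N", "L", "rpkm"])

    prefs: dict[str, int] = {}
    for c in expr_calls:
        if c.expressed:
            prefs[c.preference] = prefs.get(c.preference, 0) + 1
    report = SummaryReport(
        n_candidates=len(ds.candidates),
        n_identity_passed=sum(r.passed_identity for r in reports),
        n_nonredundant=sum(r.passed_identity and r.redundant_with is None
                           for r in reports),
        n_accepted=len(accepted),
        subfamily_counts=subfam_counts,
        chromosome_counts=chrom_counts,
        n_duplication_pairs=len(pairs),
        n_duplication_events=n_events,
        n_expressed=sum(c.expressed for c in expr_calls),
        expression_preferences=prefs,
    )
    report.recovery = score_against_truth(outputs, ds.truth)
    report.check()
    (outdir / "summary.json").write_text(report.to_json() + "\n")
    (outdir / "summary.txt").write_text(report.to_text() + "\n")
    logger.info("run_pipeline complete: %d accepted, %d expressed",
                report.n_accepted, report.n_expressed)
    return report, outputs


def score_against_truth(outputs: dict, truth) -> dict:
    """Per-stage precision/recall and exact-match fractions vs truth."""
    if not truth.genes:
        raise PipelineError("score", "empty truth table")
    fam = set(truth.genes)
    acc = {e.id for e in outputs["accepted"]}
    known = fam | set(truth.decoy_ids)
    if not acc <= known:
        raise PipelineError("score", f"unknown ids in outputs: "
                            f"{sorted(acc - known)[:3]}")
    tp = len(acc & fam)
    out = {
        "identification_precision": tp / len(acc) if acc else 0.0,
        "identification_recall": tp / len(fam),
    }
    calls = outputs.get("calls")
    if calls is not None:
        lab = {c.protein_id: c.subfamily for c in calls}
        ok = sum(1 for g in acc & fam
                 if lab.get(g) == truth.genes[g].subfamily)
        out["classification_exact"] = ok / tp if tp else 0.0
    chains = outputs.get("chains")
    if chains is not None:
        exact = sum(
            1 for c in chains if c.gene_id in fam
            and truth.genes[c.gene_id].annotation is not None
            and c.exons == truth.genes[c.gene_id].annotation.exons
            and c.strand == truth.genes[c.gene_id].annotation.strand)
        out["structure_exact"] = exact / len(chains) if chains else 0.0
    pairs = outputs.get("pairs")
    if pairs is not None:
        called = {tuple(sorted((p.gene_a, p.gene_b))) for p in pairs}
        planted = set(truth.duplication_pairs())
        ptp = len(called & planted)
        out["duplication_precision"] = ptp / len(called) if called else 1.0
        out["duplication_recall"] = ptp / len(planted) if planted else 1.0
    expr_calls = outputs.get("expression_calls")
    if expr_calls is not None:
        called_on = {c.gene_id for c in expr_calls if c.expressed}
        truth_on = set(truth.expressed_ids())
        etp = len(called_on & truth_on)
        out["expression_precision"] = (etp / len(called_on)
                                       if called_on else 1.0)
        out["expression_recall"] = etp / len(truth_on) if truth_on else 1.0
    return {k: round(v, 4) for k, v in out.items()}
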
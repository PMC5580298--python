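"""End-to-end orchestration: simulate -> phenotype -> quantify -> match ->
filter -> genetics, with reproducible configuration and file outputs.

The pipeline is deterministic given the configuration seed: every output
TSV carries a comment header with the seed and a hash of the full
configuration, and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly_match import DEFAULT_K, DEFAULT_MIN_CONTAINMENT, MatchTable, match_assemblies
from .bsa_filter import Bulks, CandidateReport, FilterParams, assign_bulks, run_candidate_filter
from .fixtures import write_fixtures
from .genetics import GeneticModel, SegregationTest, binomial_segregation_test, expected_producer_fraction, marker_cosegregation
from .phenotyping import call_producers, producer_fraction
from .quantification import compute_rpkm
from .simdata import NONPRODUCER_PARENT_ID, PRODUCER_PARENT_ID, SimConfig, SimulatedStudy, simulate_cross

ALL_STAGES = ("simulate", "phenotype", "quantify", "match", "filter", "genetics")


@dataclass
class RunConfig:
    """Single-document run configuration (JSON-serializable)."""

    sim: SimConfig = field(default_factory=SimConfig)
    filter_params: FilterParams = field(default_factory=FilterParams)
    outdir: str = "bsaseq_run"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    detection_threshold: float | None = None  # default: sim.ma_detection_threshold
    min_harvests: int = 1
    match_k: int = DEFAULT_K
    match_min_containment: float = DEFAULT_MIN_CONTAINMENT
    seed: int | None = None  # overrides sim.seed when given

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in ALL_STAGES:
            self.stages.setdefault(s, True)
        if self.seed is not None:
            self.sim = SimConfig(**{**self.sim.to_dict(), "seed": int(self.seed),
                                    "contig_length_range": self.sim.contig_length_range})

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if "sim" in data:
            sim = data["sim"]
            if "contig_length_range" in sim:
                sim["contig_length_range"] = tuple(sim["contig_length_range"])
            data["sim"] = SimConfig(**sim)
        if "filter_params" in data:
            data["filter_params"] = FilterParams(**data["filter_params"])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "filter_params": self.filter_params.to_dict(),
            "outdir": self.outdir,
            "stages": dict(self.stages),
            "detection_threshold": self.detection_threshold,
            "min_harvests": self.min_harvests,
            "match_k": self.match_k,
            "match_min_containment": self.match_min_containment,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        # hash the scientific configuration only: the same study written
        # to a different directory is still the same run
        d = self.to_dict()
        d.pop("outdir")
        canon = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, int]
    candidates: list[str]
    planted: list[str]
    segregation: dict[str, dict]
    producer_fraction_percent: float | None
    coseg: dict | None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


@dataclass
class StudyAnalysis:
    """In-memory results of analyzing one simulated study."""

    calls: list
    bulks: Bulks
    rpkm: object
    match_table: MatchTable | None
    report: CandidateReport

    @property
    def candidate_ids(self) -> list[str]:
        return self.report.candidate_ids


def analyze_study(
    study: SimulatedStudy,
    params: FilterParams | None = None,
    detection_threshold: float | None = None,
    min_harvests: int = 1,
    match_k: int = DEFAULT_K,
    match_min_containment: float = DEFAULT_MIN_CONTAINMENT,
) -> StudyAnalysis:
    """Run phenotype calling, bulk assignment, RPKM quantification and the
    candidate filter cascade on a simulated study.

    The dual-assembly check is evaluated lazily: only contigs that
    already pass the expression filters are matched against the second
    assembly (a per-contig membership test, so candidate decisions are
    identical to matching the full assembly, at a fraction of the cost).
    """
    params = params or FilterParams()
    thr = study.config.ma_detection_threshold if detection_threshold is None else detection_threshold
    calls = call_producers(study.subset_phenotypes(), detection_threshold=thr, min_harvests=min_harvests)
    bulks = assign_bulks(
        calls,
        study.subset_ids,
        producer_parent=PRODUCER_PARENT_ID if PRODUCER_PARENT_ID in study.subset_ids else None,
        nonproducer_parent=NONPRODUCER_PARENT_ID if NONPRODUCER_PARENT_ID in study.subset_ids else None,
    )
    rpkm = compute_rpkm(study.expression["A"])

    match_table = None
    if params.require_dual_assembly:
        pre_params = FilterParams(**{**params.to_dict(), "require_dual_assembly": False})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = run_candidate_filter(rpkm, bulks, None, pre_params)
        survivors = pre.candidate_ids
        if survivors:
            subset = study.assemblies["A"].subset(survivors)
            match_table = match_assemblies(subset, study.assemblies["B"], k=match_k, min_containment=match_min_containment)
        else:
            match_table = MatchTable.empty(k=match_k, min_containment=match_min_containment)
    report = run_candidate_filter(rpkm, bulks, match_table, params)
    return StudyAnalysis(calls=calls, bulks=bulks, rpkm=rpkm, match_table=match_table, report=report)


def segregation_analysis(study: SimulatedStudy, detection_threshold: float | None = None, min_harvests: int = 1) -> dict:
    """Producer fraction over the full progeny set and exact segregation
    tests against the one- and two-locus expectations."""
    thr = study.config.ma_detection_threshold if detection_threshold is None else detection_threshold
    progeny_records = [r for r in study.phenotypes if r.genotype_id not in (PRODUCER_PARENT_ID, NONPRODUCER_PARENT_ID)]
    calls = call_producers(progeny_records, detection_threshold=thr, min_harvests=min_harvests)
    frac = producer_fraction(calls)
    out = {
        "k": frac.n_producers,
        "n": frac.n_total,
        "percent": frac.percent,
        "percent_rounded": frac.percent_rounded,
        "models": {},
    }
    for model in ("one_locus", "two_locus"):
        p0 = expected_producer_fraction(GeneticModel(model))
        test = binomial_segregation_test(frac.n_producers, frac.n_total, p0)
        out["models"][model] = {
            "p0": p0,
            "p_value": test.p_value,
            "ci_low": test.ci_low,
            "ci_high": test.ci_high,
        }
    return out


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the enabled stages in dependency order, writing declared
    files under ``config.outdir``; returns the machine-readable summary
    (also written as ``summary.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.config_hash()}", f"seed={config.sim.seed}", f"bsaseq={__version__}"]
    stage_counts: dict[str, int] = {}
    candidates: list[str] = []
    planted: list[str] = []
    segregation: dict = {}
    pct = None
    coseg_out = None

    study = None
    if config.stages.get("simulate", True):
        try:
            study = simulate_cross(config.sim)
        except Exception as exc:  # pragma: no cover - defensive stage tagging
            raise RuntimeError(f"stage simulate failed: {exc}") from exc
        study.write(out, header_comments=header)
        stage_counts["simulate"] = len(study.genotypes)
        planted = list(study.truth["causal_contigs"]["A"])

    analysis = None
    if study is not None and config.stages.get("filter", True):
        analysis = analyze_study(
            study,
            params=config.filter_params,
            detection_threshold=config.detection_threshold,
            min_harvests=config.min_harvests,
            match_k=config.match_k,
            match_min_containment=config.match_min_containment,
        )
        if config.stages.get("phenotype", True):
            from .phenotyping import calls_to_tsv

            calls_to_tsv(analysis.calls, out / "producer_calls.tsv", header)
            stage_counts["phenotype"] = len(analysis.calls)
        if config.stages.get("quantify", True):
            analysis.rpkm.to_tsv(out / "rpkm_A.tsv", header)
            stage_counts["quantify"] = len(analysis.rpkm.contig_ids)
        if config.stages.get("match", True) and analysis.match_table is not None:
            analysis.match_table.to_tsv(out / "match.tsv", header)
            stage_counts["match"] = len(analysis.match_table.pairs)
        analysis.report.to_tsv(out / "candidate_report.tsv", header)
        with open(out / "filter_summary.json", "w", encoding="utf-8") as fh:
            json.dump(analysis.report.summary(), fh, indent=1, sort_keys=True)
        stage_counts["filter"] = len(analysis.report.candidate_ids)
        candidates = analysis.report.candidate_ids

    if study is not None and config.stages.get("genetics", True):
        segregation = segregation_analysis(study, config.detection_threshold, config.min_harvests)
        pct = segregation["percent"]
        marker = dict(zip(study.marker_table["genotype_id"], study.marker_table["band_1500_present"]))
        transcript = {g: study.truth["carriers"][g] for g in study.subset_ids}
        table = marker_cosegregation(marker, transcript)
        coseg_out = {
            "n11": table.n11,
            "n10": table.n10,
            "n01": table.n01,
            "n00": table.n00,
            "concordance": table.concordance,
            "exact_p": table.exact_p,
        }
        with open(out / "genetics.json", "w", encoding="utf-8") as fh:
            json.dump({"segregation": segregation, "marker_cosegregation": coseg_out}, fh, indent=1, sort_keys=True)
        stage_counts["genetics"] = segregation["n"]

    summary = RunSummary(
        config_hash=config.config_hash(),
        seed=config.sim.seed,
        version=__version__,
        stage_counts=stage_counts,
        candidates=candidates,
        planted=planted,
        segregation=segregation,
        producer_fraction_percent=pct,
        coseg=coseg_out,
    )
    summary.to_json(out / "summary.json")
    return summary


def make_fixtures(outdir=None) -> list[Path]:
    """Write the packaged worked-example fixtures (candidate RPKM table,
    segregation counts, marker co-segregation) to ``outdir``."""
    outdir = Path(outdir) if outdir is not None else Path("fixtures")
    return write_fixtures(outdir)
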
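"""End-to-end orchestration: corpus -> lifetime -> term filters ->
correlation -> Pathfinder backbone -> decorated, laid-out network.

The stages run in a fixed order and the run report records the term
funnel (initial -> after routine removal -> emerging) together with every
parameter that shaped the result, so a run is auditable and exactly
repeatable from its report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx

from . import corpus_io, lifetime, network, pfnet, selection, similarity
from .corpus_io import Corpus

__all__ = ["RunConfig", "RunReport", "PipelineError", "run"]

log = logging.getLogger("meshnet")


class PipelineError(Exception):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.  Exactly one input source."""

    input_xml: str | None = None
    fixture: str | None = None
    query: str | None = None

    y_last: int | None = None  # default: newest complete year in the corpus
    window_years: int = 3
    min_avg: float = 10.0
    min_final_count: int = 3
    mode: str = "title"  # or "cooccurrence"
    mesh_tree_file: str | None = None
    out_dir: str | None = None
    formats: tuple[str, ...] = ("graphml",)
    seed: int = network.DEFAULT_LAYOUT_SEED
    contact_email: str = ""

    def __post_init__(self) -> None:
        sources = [s for s in (self.input_xml, self.fixture, self.query) if s]
        if len(sources) != 1:
            raise ValueError("exactly one of input_xml, fixture, query is required")
        if self.mode not in ("title", "cooccurrence"):
            raise ValueError("mode must be 'title' or 'cooccurrence'")


@dataclass
class RunReport:
    """What a run did and found; serializable to JSON."""

    config: dict = field(default_factory=dict)
    n_records: int = 0
    y_last: int = 0
    n_periods: int = 0
    lifetime_years: int = 0
    period_bounds: list[tuple[int, int]] = field(default_factory=list)
    period_averages: list[float] = field(default_factory=list)
    n_initial_terms: int = 0
    n_after_routine_removal: int = 0
    n_emerging_terms: int = 0
    n_keywords: int = 0
    n_edges: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n",
                              encoding="utf-8")


@dataclass
class RunResult:
    report: RunReport
    graph: nx.Graph
    positions: Mapping
    emerging_terms: list[str]
    sim: similarity.SimilarityMatrix
    table: selection.TermCountTable


def _load_corpus(config: RunConfig) -> Corpus:
    if config.fixture:
        return corpus_io.read_fixture(config.fixture)
    if config.input_xml:
        return corpus_io.parse_pubmed_xml(config.input_xml)
    return corpus_io.fetch_entrez(config.query, {"email": config.contact_email})


def run(config: RunConfig, corpus: Corpus | None = None) -> RunResult:
    """Execute the full pipeline.

    ``corpus`` may be supplied directly (e.g. a synthetic corpus),
    bypassing the configured input source.  Raises :class:`PipelineError`
    with the failing stage's name on any abort.
    """
    report = RunReport(config=asdict(config))
    timer = _StageTimer(report)

    with timer("corpus"):
        if corpus is None:
            try:
                corpus = _load_corpus(config)
            except corpus_io.CorpusError as exc:
                raise PipelineError("corpus", str(exc)) from exc
        report.n_records = len(corpus)
        log.info("corpus: %d records (%s)", len(corpus), corpus.provenance)

    with timer("lifetime"):
        counts = lifetime.annual_counts(corpus)
        if not counts:
            raise PipelineError("lifetime", "corpus has no records")
        y_last = config.y_last if config.y_last is not None else lifetime.default_y_last(counts)
        cfg = lifetime.LifetimeConfig(y_last=y_last,
                                      window_years=config.window_years,
                                      min_avg=config.min_avg)
        periods = lifetime.build_time_periods(counts, cfg)
        if not periods:
            raise PipelineError(
                "lifetime",
                f"no eligible time period: the newest {config.window_years}-year "
                f"window ending {y_last} has annual average <= {config.min_avg}",
            )
        report.y_last = y_last
        report.n_periods = len(periods)
        report.lifetime_years = lifetime.lifetime_years(periods)
        report.period_bounds = [(p.start_year, p.end_year) for p in periods]
        report.period_averages = [round(p.avg_count, 1) for p in periods]
        log.info("lifetime: N=%d periods, %d years", len(periods),
                 report.lifetime_years)
        # Records newer than y_last are excluded from all later stages.
        corpus = corpus.restrict_years(periods[0].start_year, y_last)

    with timer("term-selection"):
        table = selection.count_mesh_by_period(corpus, periods)
        report.n_initial_terms = len(table.terms)
        try:
            pruned_table = selection.remove_routine(table)
        except ValueError as exc:
            raise PipelineError("routine-removal", str(exc)) from exc
        report.n_after_routine_removal = len(pruned_table.terms)
        emerging = selection.select_emerging(
            pruned_table, selection.SelectionConfig(config.min_final_count))
        report.n_emerging_terms = len(emerging)
        log.info("terms: %d initial -> %d after routine removal -> %d emerging",
                 report.n_initial_terms, report.n_after_routine_removal,
                 report.n_emerging_terms)
        if len(emerging) < 2:
            raise PipelineError(
                "emerging-selection",
                f"only {len(emerging)} emerging term(s); relax --min-final-count "
                f"(currently {config.min_final_count}) or --min-avg to widen the set",
            )

    with timer("correlation"):
        final = periods[-1]
        corpus_tn = corpus.restrict_years(final.start_year, final.end_year)
        if config.mode == "title":
            vocabulary = similarity.corpus_keywords(corpus)
            report.n_keywords = len(vocabulary)
            mtx = similarity.build_mesh_tk_matrix(corpus_tn, emerging, vocabulary)
            sim = similarity.similarity_matrix(mtx)
        else:
            sim = similarity.cooccurrence_matrix(corpus_tn, emerging)

    with timer("pfnet"):
        graph = pfnet.prune(sim)
        report.n_edges = graph.number_of_edges()
        log.info("pfnet: %d nodes, %d edges", graph.number_of_nodes(),
                 report.n_edges)

    with timer("layout"):
        category_map = (network.load_category_map(config.mesh_tree_file)
                        if config.mesh_tree_file else {})
        final_counts = {t: int(pruned_table.row(t)[-1]) for t in emerging}
        network.decorate(graph, final_counts, category_map)
        positions = network.layout(graph, seed=config.seed)

    if config.out_dir:
        with timer("export"):
            _export(config, report, graph, positions, table, sim)

    return RunResult(report=report, graph=graph, positions=positions,
                     emerging_terms=emerging, sim=sim, table=table)


def _export(config, report, graph, positions, table, sim) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "term_counts.tsv",
                 selection.SelectionConfig(config.min_final_count))
    sim.to_tsv(out / "similarity.tsv")
    report.artifacts += ["term_counts.tsv", "similarity.tsv"]
    if "graphml" in config.formats:
        network.export_graphml(graph, positions, out / "mesh_net.graphml")
        report.artifacts.append("mesh_net.graphml")
    if "tsv" in config.formats:
        network.export_edgelist_tsv(graph, out / "mesh_net_edges.tsv")
        report.artifacts.append("mesh_net_edges.tsv")
    if "png" in config.formats:
        network.export_png(graph, positions, out / "mesh_net.png")
        report.artifacts.append("mesh_net.png")
    report.to_json(out / "run_report.json")


class _StageTimer:
    def __init__(self, report: RunReport):
        self.report = report

    def __call__(self, stage: str):
        return _Timing(self.report, stage)


class _Timing:
    def __init__(self, report: RunReport, stage: str):
        self.report, self.stage = report, stage

    def __enter__(self):
        self.t0 = time.perf_counter()

    def __exit__(self, *exc):
        self.report.stage_seconds[self.stage] = round(
            time.perf_counter() - self.t0, 4)
        return False
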
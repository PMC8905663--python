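"""End-to-end orchestration: screen → network → score → select → enrich.

The pure-computation entry point is :func:`run_analysis`, which takes the
in-memory inputs and returns every intermediate stage in one result
object.  :func:`run_all` is its file-based wrapper: it reads the inputs
named in a :class:`PipelineConfig`, runs the analysis and writes the
stage tables plus a run manifest.  Stage outputs are pure functions of
inputs + config + seed, so re-running is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .adme import ScreenReport, screen_components
from .contribution import (
    ContributionScore,
    ContributionTerms,
    FunctionalSpace,
    compute_terms,
    contribution_scores,
    select_functional_space,
)
from .enrichment import EnrichmentResult, enrich
from .io_core import (
    ComponentRecord,
    EdgeTable,
    HerbDose,
    RunManifest,
    components_to_frame,
    read_component_table,
    read_dose_table,
    read_edge_table,
    read_gmt,
    sha256_file,
    write_results,
)
from .knapsack import (
    KnapsackItem,
    KnapsackSolution,
    attach_coverage,
    build_items,
    capacity_from_fraction,
    solve_knapsack,
)
from .network import (
    BipartiteCTNetwork,
    ConvergedNetwork,
    build_ct_network,
    converge_with_ppi,
    median_degree_filter,
)

log = logging.getLogger(__name__)


def _resolve_edge_sources(
    records: list[ComponentRecord], ct_edges: EdgeTable
) -> EdgeTable:
    """Map edge sources given as component names onto record ids.

    Edge lists commonly reference components by their printed name rather
    than the reader's id.  An exact id match wins; otherwise the
    (normalized) name resolves the source — a name carried by several
    records fans the edge out to each of them.  Unresolvable sources are
    left untouched (they are dropped later with the screened-out set).
    """
    from .io_core import normalize_name

    ids = {r.component_id for r in records}
    by_name: dict[str, list[str]] = {}
    for r in records:
        by_name.setdefault(normalize_name(r.name), []).append(r.component_id)
    out: list[tuple[str, str]] = []
    unresolved = 0
    for src, tgt in ct_edges.edges:
        if src in ids:
            out.append((src, tgt))
        elif normalize_name(src) in by_name:
            out.extend((cid, tgt) for cid in by_name[normalize_name(src)])
        else:
            unresolved += 1
            out.append((src, tgt))
    if unresolved:
        log.warning("%d edge source(s) match no component id or name", unresolved)
    # fan-out can duplicate pairs; collapse keeping order
    seen: set[tuple[str, str]] = set()
    deduped = tuple(e for e in out if not (e in seen or seen.add(e)))
    return EdgeTable(edges=deduped, kind=ct_edges.kind)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    components: str | None = None
    ct_edges: str | None = None
    ppi_edges: str | None = None
    doses: str | None = None
    gmt: str | None = None
    disease_genes: str | None = None
    out_dir: str = "cfcg_out"
    fraction_space: float = 0.90
    fraction_capacity: float = 0.90
    tar_mode: str = "per_target"  # "per_target" | "summed"
    ecc_network: str = "ct"  # "ct" | "converged" — eccentricity source for CSC
    merge: str = "by-name"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("fraction_space", "fraction_capacity"):
            v = getattr(self, f)
            if not (0 < v <= 1):
                raise ValueError(f"{f} must be in (0, 1]")


@dataclass
class PipelineResult:
    screened: list[ComponentRecord]
    screen_report: ScreenReport
    net: BipartiteCTNetwork
    terms: list[ContributionTerms]
    scores: list[ContributionScore]
    space: FunctionalSpace
    converged: ConvergedNetwork
    retained_targets: set[str]
    median_degree: float
    items: list[KnapsackItem]
    capacity: int
    cfcg: KnapsackSolution
    enrichment: list[EnrichmentResult] = field(default_factory=list)


def run_analysis(
    records: list[ComponentRecord],
    ct_edges: EdgeTable,
    ppi_edges: EdgeTable | None,
    doses: list[HerbDose],
    cfg: PipelineConfig,
    annotation=None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    1. rule-of-five screen;
    2. C-T network on the survivors (edges to screened-out components drop);
    3. contribution terms and scores, functional-space prefix;
    4. converged network on the space subgraph, median-degree filter,
       knapsack items, capacity and selection;
    5. optional enrichment of the selection's covered targets.
    """
    screened, report = screen_components(records)
    if not screened:
        raise ValueError("no component passed the rule-of-five screen")
    ct_edges = _resolve_edge_sources(records, ct_edges)
    keep = {r.component_id for r in screened}
    edges = EdgeTable(
        edges=tuple(e for e in ct_edges.edges if e[0] in keep), kind=ct_edges.kind
    )
    net = build_ct_network(screened, edges)

    ppi = ppi_edges or EdgeTable(edges=(), kind="target-target")
    ecc_net = converge_with_ppi(net, ppi) if cfg.ecc_network == "converged" else None
    terms = compute_terms(net, screened, doses, ecc_net=ecc_net)
    scores = contribution_scores(terms, tar_mode=cfg.tar_mode)
    space = select_functional_space(scores, terms, fraction=cfg.fraction_space)

    # converged network restricted to the functional space and its targets
    space_ids = set(space.component_ids)
    space_records = [r for r in screened if r.component_id in space_ids]
    space_edges = EdgeTable(
        edges=tuple(e for e in edges.edges if e[0] in space_ids), kind=edges.kind
    )
    space_net = build_ct_network(space_records, space_edges)
    conv = converge_with_ppi(space_net, ppi)
    retained, median = median_degree_filter(conv, conv.components, conv.targets)
    if not retained:
        raise ValueError("median-degree filter retained no targets")

    items = build_items(sorted(space_ids), retained, conv)
    capacity = capacity_from_fraction(len(retained), cfg.fraction_capacity)
    solution = attach_coverage(solve_knapsack(items, capacity), conv, retained)

    enr: list[EnrichmentResult] = []
    if annotation:
        cfcg_targets = set()
        for cid in solution.selected_ids:
            cfcg_targets.update(conv.targets_of(cid))
        enr = enrich({t.upper() for t in cfcg_targets}, annotation, alpha=cfg.alpha)

    return PipelineResult(
        screened=screened, screen_report=report, net=net, terms=terms,
        scores=scores, space=space, converged=conv, retained_targets=retained,
        median_degree=median, items=items, capacity=capacity, cfcg=solution,
        enrichment=enr,
    )


def result_tables(res: PipelineResult) -> dict[str, pd.DataFrame]:
    """Flatten a result into the TSV tables the pipeline writes."""
    terms_by_id = {t.component_id: t for t in res.terms}
    scores_df = pd.DataFrame(
        [
            {
                "component_id": s.component_id,
                "rank": s.rank,
                "csc": s.csc,
                "share": s.share,
                "cumulative_share": s.cumulative_share,
                "comp_ecc": terms_by_id[s.component_id].comp_ecc,
                "ecc_herb_a": terms_by_id[s.component_id].comp_ecc_herb_a,
                "ecc_herb_b": terms_by_id[s.component_id].comp_ecc_herb_b,
                "c_edge": terms_by_id[s.component_id].c_edge,
                "t_edge": terms_by_id[s.component_id].t_edge,
                "asymmetry": terms_by_id[s.component_id].asymmetry,
                "dose": terms_by_id[s.component_id].dose,
                "dose_mode": terms_by_id[s.component_id].dose_mode,
                "in_space": s.component_id in set(res.space.component_ids),
            }
            for s in res.scores
        ]
    )
    items_by_id = {it.component_id: it for it in res.items}
    cfcg_df = pd.DataFrame(
        [
            {
                "component_id": cid,
                "weight_retained_targets": items_by_id[cid].weight,
                "value_sum_degree": items_by_id[cid].value,
            }
            for cid in res.cfcg.selected_ids
        ]
    )
    enr_df = pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name, "k": r.k,
                "q": r.q, "m": r.m, "universe": r.universe,
                "pvalue": r.pvalue, "adj_pvalue": r.adj_pvalue,
                "significant": r.significant,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in res.enrichment
        ]
    )
    return {
        "screened_components": components_to_frame(res.screened),
        "contribution_scores": scores_df,
        "cfcg": cfcg_df,
        "enrichment": enr_df,
    }


def run_all(cfg: PipelineConfig) -> tuple[Path, RunManifest]:
    """File-based full run; writes stage TSVs plus ``manifest.json``.

    On a stage failure the partial outputs stay in place next to a
    ``FAILED`` marker naming the stage and cause.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        if not cfg.components or not cfg.ct_edges or not cfg.doses:
            raise ValueError("components, ct_edges and doses paths are required")
        records = read_component_table(cfg.components, merge=cfg.merge)
        ct = read_edge_table(cfg.ct_edges, kind="component-target")
        ppi = (
            read_edge_table(cfg.ppi_edges, kind="target-target")
            if cfg.ppi_edges else None
        )
        doses = read_dose_table(cfg.doses)
        annotation = read_gmt(cfg.gmt) if cfg.gmt else None

        stage = "analysis"
        res = run_analysis(records, ct, ppi, doses, cfg, annotation=annotation)

        stage = "write-results"
        manifest = RunManifest(
            inputs={
                p: sha256_file(p)
                for p in (cfg.components, cfg.ct_edges, cfg.ppi_edges,
                          cfg.doses, cfg.gmt)
                if p
            },
            # out_dir is where results land, not an input of the computation;
            # leaving it out keeps equal-input runs byte-identical
            config={k: v for k, v in asdict(cfg).items() if k != "out_dir"},
            seed=cfg.seed,
            version=__version__,
        )
        write_results(result_tables(res), out, manifest)
        marker = out / "FAILED"
        if marker.exists():
            marker.unlink()
        log.info("pipeline finished: %d CFCG component(s), capacity %d",
                 res.cfcg.n_selected, res.capacity)
        return out, manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n", encoding="utf-8")
        raise
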
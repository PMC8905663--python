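"""Synthetic two-herb datasets with planted structure.

The generator emulates the qualitative features the pipeline exploits in
real formula data: a bipartite component–target network in which a pool
of *shared* targets is reachable from both herbs and carries higher
degree than herb-private targets (shared targets as hubs), plus a small
*planted core* of components that attach preferentially to those hubs.
A pipeline that ranks components by network contribution and then selects
a minimal high-coverage group should recover the planted core.

Everything is drawn from one seeded generator, so a given config is
byte-reproducible.  What the generator does **not** emulate: real
chemistry (properties are drawn uniformly inside/outside the rule-of-five
box), scale-free PPI topology (Erdős–Rényi), or curated annotations
(terms are random target subsets plus one hub-concentrated term).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import AnnotationTerm, ComponentRecord, EdgeTable, HerbDose

__all__ = ["SynthConfig", "SynthTruth", "SynthDataset", "generate_dataset",
           "write_dataset", "recovery_experiment", "RecoveryResult"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults give a small strong-signal dataset."""

    seed: int
    n_herbs: int = 2
    components_per_herb: int = 15
    fraction_shared_components: float = 0.0  # components listed under both herbs
    n_targets: int = 120
    fraction_shared_targets: float = 0.25  # hub pool reachable from both herbs
    fraction_superhubs: float = 0.33  # top tier of the shared pool; the core's home
    core_size: int = 3  # planted core components (split across herbs)
    hub_degree_multiplier: float = 5.0  # sampling weight of hub targets; ≥5 = strong signal
    degree_range: tuple[int, int] = (3, 6)  # targets per ordinary component
    core_degree_range: tuple[int, int] = (4, 5)  # super-hub targets per core component
    ppi_edge_prob: float = 0.01  # background PPI density
    ppi_hub_prob: float = 0.50  # PPI density on shared pairs touching a super-hub
    dose_range: tuple[float, float] = (10.0, 20.0)  # grams of herb
    concentration_range: tuple[float, float] = (0.1, 5.0)  # mg/g, ordinary
    core_concentration_range: tuple[float, float] = (20.0, 80.0)  # mg/g, core
    adme_fail_fraction: float = 0.2  # ordinary components given one failing property
    n_annotation_terms: int = 12
    herb_labels: tuple[str, str] = ("herbA", "herbB")

    def validate(self) -> None:
        if self.n_herbs != 2:
            raise ValueError("generator supports exactly two herbs")
        if self.core_size > self.n_herbs * self.components_per_herb:
            raise ValueError("planted core larger than the component universe")
        for p in (self.fraction_shared_components, self.fraction_shared_targets,
                  self.ppi_edge_prob, self.adme_fail_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.components_per_herb < 1 or self.n_targets < 2:
            raise ValueError("need at least one component per herb and two targets")


@dataclass
class SynthTruth:
    """Ground truth of the planted structure."""

    core_component_ids: tuple[str, ...]
    shared_target_ids: tuple[str, ...]
    targets_of: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class SynthDataset:
    records: list[ComponentRecord]
    ct_edges: EdgeTable
    ppi_edges: EdgeTable
    doses: list[HerbDose]
    annotation: list[AnnotationTerm]
    disease_genes: tuple[str, ...]


def _passing_properties(rng: np.random.Generator) -> dict:
    return dict(
        mw=round(float(rng.uniform(100, 480)), 2),
        rbn=int(rng.integers(0, 11)),
        n_hacc=int(rng.integers(0, 10)),
        n_hdon=int(rng.integers(0, 5)),
        clogp=round(float(rng.uniform(-1.9, 4.9)), 2),
    )


def _fail_one_rule(props: dict, rng: np.random.Generator) -> dict:
    rule = rng.integers(0, 5)
    props = dict(props)
    if rule == 0:
        props["mw"] = round(float(rng.uniform(500, 900)), 2)
    elif rule == 1:
        props["rbn"] = int(rng.integers(11, 20))
    elif rule == 2:
        props["n_hacc"] = int(rng.integers(10, 16))
    elif rule == 3:
        props["n_hdon"] = int(rng.integers(5, 10))
    else:
        props["clogp"] = round(float(rng.choice([-1, 1]) * rng.uniform(5.0, 8.0)), 2)
    return props


def generate_dataset(cfg: SynthConfig) -> tuple[SynthDataset, SynthTruth]:
    """Draw one complete input set plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    herb_a, herb_b = cfg.herb_labels

    # --- targets: two-tier shared hub pool + two private pools -------------
    # super-hubs are the top tier every component is drawn toward and the
    # planted core covers exclusively; they end up with the highest degree.
    n_shared = int(round(cfg.fraction_shared_targets * cfg.n_targets))
    target_ids = [f"t{i:03d}" for i in range(cfg.n_targets)]
    shared_targets = target_ids[:n_shared]
    n_super = max(1, int(round(cfg.fraction_superhubs * n_shared))) if n_shared else 0
    superhubs = shared_targets[:n_super]
    regular_hubs = shared_targets[n_super:]
    private = target_ids[n_shared:]
    half = len(private) // 2
    pool = {herb_a: private[:half], herb_b: private[half:]}

    # --- components --------------------------------------------------------
    n_per = cfg.components_per_herb
    n_shared_comps = int(round(cfg.fraction_shared_components * n_per))
    comp_herbs: list[tuple[str, frozenset[str]]] = []
    for k in range(n_shared_comps):
        comp_herbs.append((f"cS{k:02d}", frozenset({herb_a, herb_b})))
    for herb, tag in ((herb_a, "cA"), (herb_b, "cB")):
        for k in range(n_per - n_shared_comps):
            comp_herbs.append((f"{tag}{k:02d}", frozenset({herb})))

    core_ids = []
    for i in range(cfg.core_size):  # alternate herbs so the core spans both
        herb = cfg.herb_labels[i % 2]
        tag = "cA" if herb == herb_a else "cB"
        core_ids.append(f"{tag}{i // 2:02d}")
    core_ids = sorted(set(core_ids))
    if len(core_ids) < cfg.core_size:
        raise ValueError("could not place the full planted core")

    records: list[ComponentRecord] = []
    edges: list[tuple[str, str]] = []
    truth_targets: dict[str, tuple[str, ...]] = {}
    for cid, herbs in comp_herbs:
        is_core = cid in core_ids
        props = _passing_properties(rng)
        if not is_core and rng.random() < cfg.adme_fail_fraction:
            props = _fail_one_rule(props, rng)
        conc_lo, conc_hi = (
            cfg.core_concentration_range if is_core else cfg.concentration_range
        )
        records.append(
            ComponentRecord(
                component_id=cid, name=cid, herbs=herbs,
                concentration=round(float(rng.uniform(conc_lo, conc_hi)), 3),
                **props,
            )
        )
        # multiplier > 1 plants the signal: ordinary components are drawn
        # toward the shared hubs (super-hubs hardest), and core components
        # attach to super-hubs only.  multiplier <= 1 is the null
        # configuration: everyone samples uniformly, core included.
        mult = cfg.hub_degree_multiplier
        planted = mult > 1.0
        if is_core and planted and superhubs:
            cand: list[str] = list(superhubs)
            weights = [1.0] * len(cand)
            lo, hi = cfg.core_degree_range
        else:
            cand = sorted(set().union(*(pool[h] for h in herbs)))
            weights = [1.0] * len(cand)
            cand += regular_hubs
            weights += [mult if planted else 1.0] * len(regular_hubs)
            cand += superhubs
            weights += [max(mult, 1.0) / 2 if planted else 1.0] * len(superhubs)
            lo, hi = cfg.degree_range
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(cand))
        w = np.asarray(weights) / np.sum(weights)
        chosen = sorted(rng.choice(cand, size=k, replace=False, p=w))
        truth_targets[cid] = tuple(chosen)
        edges.extend((cid, t) for t in chosen)

    used_targets = sorted({t for _, t in edges})

    # --- PPI: dense among shared hubs, sparse elsewhere --------------------
    # the hub-hub density is what makes shared targets high-degree in the
    # converged network — the signature the median filter keys on.
    shared_set = set(shared_targets)
    super_set = set(superhubs)
    ppi: list[tuple[str, str]] = []
    for i in range(len(target_ids)):
        for j in range(i + 1, len(target_ids)):
            a, b = target_ids[i], target_ids[j]
            if a in shared_set and b in shared_set:
                touches_super = a in super_set or b in super_set
                p = cfg.ppi_hub_prob if touches_super else cfg.ppi_hub_prob / 4
            else:
                p = cfg.ppi_edge_prob
            if rng.random() < p:
                ppi.append((a, b))

    # --- doses --------------------------------------------------------------
    doses = [
        HerbDose(h, round(float(rng.uniform(*cfg.dose_range)), 1))
        for h in cfg.herb_labels
    ]

    # --- annotation: random terms + one hub-concentrated term --------------
    terms: list[AnnotationTerm] = []
    if shared_targets:
        terms.append(AnnotationTerm("TERM_HUB", "planted hub pathway",
                                    frozenset(g.upper() for g in shared_targets)))
    for i in range(cfg.n_annotation_terms):
        size = int(rng.integers(5, max(6, cfg.n_targets // 6)))
        genes = rng.choice(target_ids, size=min(size, len(target_ids)), replace=False)
        terms.append(AnnotationTerm(f"TERM{i:03d}", f"random set {i}",
                                    frozenset(g.upper() for g in genes)))
    n_dis = max(3, len(shared_targets) // 2)
    disease = sorted(
        set(rng.choice(shared_targets or used_targets, size=min(n_dis, len(shared_targets or used_targets)), replace=False))
    )

    dataset = SynthDataset(
        records=records,
        ct_edges=EdgeTable(edges=tuple(edges), kind="component-target"),
        ppi_edges=EdgeTable(edges=tuple(ppi), kind="target-target"),
        doses=doses,
        annotation=terms,
        disease_genes=tuple(g.upper() for g in disease),
    )
    truth = SynthTruth(
        core_component_ids=tuple(core_ids),
        shared_target_ids=tuple(shared_targets),
        targets_of=truth_targets,
    )
    return dataset, truth


def write_dataset(dataset: SynthDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the same text formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for r in dataset.records:
        for herb in sorted(r.herbs):
            rows.append({"name": r.name, "source": herb, "MW": r.mw, "RBN": r.rbn,
                         "nHAcc": r.n_hacc, "nHDon": r.n_hdon, "ClogP": r.clogp,
                         "concentration_mg_per_g": r.concentration})
    paths["components"] = out / "components.tsv"
    pd.DataFrame(rows).to_csv(paths["components"], sep="\t", index=False, lineterminator="\n")

    paths["ct_edges"] = out / "ct_edges.tsv"
    with open(paths["ct_edges"], "w", encoding="utf-8") as fh:
        for a, b in dataset.ct_edges.edges:
            fh.write(f"{a}\t{b}\n")
    paths["ppi_edges"] = out / "ppi_edges.tsv"
    with open(paths["ppi_edges"], "w", encoding="utf-8") as fh:
        for a, b in dataset.ppi_edges.edges:
            fh.write(f"{a}\t{b}\n")
    paths["doses"] = out / "doses.tsv"
    with open(paths["doses"], "w", encoding="utf-8") as fh:
        fh.write("herb\tgrams\n")
        for d in dataset.doses:
            fh.write(f"{d.herb}\t{d.grams}\n")
    paths["annotation"] = out / "annotation.gmt"
    with open(paths["annotation"], "w", encoding="utf-8") as fh:
        for t in dataset.annotation:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")
    paths["disease_genes"] = out / "disease_genes.txt"
    with open(paths["disease_genes"], "w", encoding="utf-8") as fh:
        fh.writelines(g + "\n" for g in dataset.disease_genes)
    return paths


@dataclass
class RecoveryResult:
    """Planted-core recovery of the full pipeline across seeds."""

    n_seeds: int
    recovery_rate: float  # fraction of seeds with core ⊆ CFCG
    mean_precision: float  # |CFCG ∩ core| / |CFCG|
    mean_recall: float  # |CFCG ∩ core| / |core|
    per_seed: list[dict] = field(default_factory=list)


def recovery_experiment(cfg: SynthConfig, n_seeds: int) -> RecoveryResult:
    """Run the full pipeline on ``n_seeds`` fresh datasets; score recovery."""
    from .pipeline import PipelineConfig, run_analysis

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    per_seed: list[dict] = []
    n_full = 0
    for k in range(n_seeds):
        seed = cfg.seed + k
        dataset, truth = generate_dataset(dataclasses.replace(cfg, seed=seed))
        try:
            result = run_analysis(
                dataset.records, dataset.ct_edges, dataset.ppi_edges,
                dataset.doses, PipelineConfig(seed=seed),
            )
        except Exception as exc:  # noqa: BLE001 — annotate with the seed
            raise RuntimeError(f"pipeline failed for seed {seed}: {exc}") from exc
        selected = set(result.cfcg.selected_ids)
        core = set(truth.core_component_ids)
        hit = core <= selected
        n_full += hit
        per_seed.append(
            {
                "seed": seed,
                "core_recovered": hit,
                "precision": len(selected & core) / len(selected) if selected else 0.0,
                "recall": len(selected & core) / len(core) if core else 1.0,
                "n_selected": len(selected),
            }
        )
    return RecoveryResult(
        n_seeds=n_seeds,
        recovery_rate=n_full / n_seeds,
        mean_precision=float(np.mean([d["precision"] for d in per_seed])),
        mean_recall=float(np.mean([d["recall"] for d in per_seed])),
        per_seed=per_seed,
    )
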
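"""Contribution scoring and coordinated functional space selection.

Each component i is scored by how much it contributes to the two-herb
formula's joint pharmacology.  For every component–target pair (i, j) a
raw edge score is formed from network topology::

    C_ij = Comp_i * (C_edge / T_edge + |Comp_Hi - Comp_Ci| / (Comp_Hi + Comp_Ci)) * Tar_j

where Comp_i is the component's eccentricity in the scoring network,
C_edge its degree, T_edge the summed degree of its targets, Comp_Hi /
Comp_Ci its eccentricities inside the two single-herb subnetworks (0 when
absent — the asymmetry ratio is then 1 for a herb-exclusive component and
0 for a perfectly symmetric one), and Tar_j the target eccentricity term.
Tar_j has two supported readings: the eccentricity of target j itself
(``tar_mode="per_target"``, default) or the summed eccentricity of all of
i's targets (``tar_mode="summed"``).

After min–max normalization of all C_ij (one global pool over every pair)
and of the per-component dose, the contribution score is::

    CSC(i) = sum over targets j of ( NL(C_ij) + NL(dose_i) )

The coordinated functional space is the shortest prefix of the
descending-CSC ranking whose cumulative share of the total reaches a set
fraction (default 0.90).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_core import ComponentRecord, HerbDose
from .network import BipartiteCTNetwork, all_eccentricities, herb_subnetwork

__all__ = [
    "ContributionTerms",
    "ContributionScore",
    "FunctionalSpace",
    "effective_dose",
    "herb_asymmetry",
    "raw_edge_score",
    "minmax_normalize",
    "compute_terms",
    "contribution_scores",
    "select_functional_space",
]

log = logging.getLogger(__name__)


@dataclass
class ContributionTerms:
    """Every symbol of the edge-score formula for one component."""

    component_id: str
    comp_ecc: int  # eccentricity in the scoring network
    comp_ecc_herb_a: int  # eccentricity in first herb's subnetwork, 0 if absent
    comp_ecc_herb_b: int  # eccentricity in second herb's subnetwork, 0 if absent
    c_edge: int  # component degree
    t_edge: int  # summed degree of the component's targets
    target_eccs: dict[str, int] = field(default_factory=dict)
    dose: float = 0.0
    dose_mode: str = "grams"  # "concentration" | "grams"

    def __post_init__(self) -> None:
        if self.c_edge != len(self.target_eccs):
            raise ValueError(
                f"{self.component_id}: c_edge ({self.c_edge}) != number of targets "
                f"({len(self.target_eccs)})"
            )
        if self.c_edge > 0 and self.t_edge < self.c_edge:
            raise ValueError(f"{self.component_id}: t_edge < c_edge is impossible")

    @property
    def n_targets(self) -> int:
        return len(self.target_eccs)

    @property
    def asymmetry(self) -> float:
        return herb_asymmetry(self.comp_ecc_herb_a, self.comp_ecc_herb_b)


@dataclass(frozen=True)
class ContributionScore:
    component_id: str
    csc: float
    rank: int
    share: float
    cumulative_share: float


@dataclass
class FunctionalSpace:
    """Top-ranked components accumulating the target share of total CSC."""

    component_ids: tuple[str, ...]
    achieved_share: float
    fraction: float
    covered_targets: frozenset[str]
    coverage_fraction: float


def effective_dose(rec: ComponentRecord, doses: list[HerbDose]) -> tuple[float, str]:
    """Dose quantity for one component.

    With a measured concentration (mg/g) the dose is the total mg in the
    formula: concentration × grams, summed over the component's herbs.
    Without one, the summed raw herb grams act as a proxy; the mode is
    returned so reports can flag which convention produced the number.
    """
    grams = {d.herb: d.grams for d in doses}
    missing = sorted(h for h in rec.herbs if h not in grams)
    if missing:
        raise ValueError(f"{rec.component_id}: no dose for herb(s) {', '.join(missing)}")
    total_grams = sum(grams[h] for h in rec.herbs)
    if rec.concentration is not None:
        return rec.concentration * total_grams, "concentration"
    return total_grams, "grams"


def herb_asymmetry(ecc_a: float, ecc_b: float) -> float:
    """|a − b| / (a + b) in [0, 1]; 0 when both are 0.

    Equals 1 exactly when one herb eccentricity is 0 and the other is not,
    i.e. for a herb-exclusive component.
    """
    if ecc_a < 0 or ecc_b < 0:
        raise ValueError("eccentricities must be non-negative")
    if ecc_a == 0 and ecc_b == 0:
        return 0.0
    return abs(ecc_a - ecc_b) / (ecc_a + ecc_b)


def raw_edge_score(terms: ContributionTerms, target: str, tar_mode: str = "per_target") -> float:
    """The raw C_ij score for one component–target pair."""
    if target not in terms.target_eccs:
        raise ValueError(f"{terms.component_id}: unknown target {target!r}")
    if terms.t_edge == 0:
        log.warning("raw_edge_score: %s is isolated (t_edge=0); score 0", terms.component_id)
        return 0.0
    if tar_mode == "per_target":
        tar = terms.target_eccs[target]
    elif tar_mode == "summed":
        tar = sum(terms.target_eccs.values())
    else:
        raise ValueError(f"unknown tar_mode {tar_mode!r}")
    return terms.comp_ecc * (terms.c_edge / terms.t_edge + terms.asymmetry) * tar


def minmax_normalize(values: list[float]) -> list[float]:
    """(x − min) / (max − min); an all-equal pool maps to all zeros."""
    if not values:
        raise ValueError("cannot normalize an empty pool")
    lo, hi = min(values), max(values)
    if hi == lo:
        log.info("minmax_normalize: degenerate constant pool (n=%d) -> zeros", len(values))
        return [0.0 for _ in values]
    return [(v - lo) / (hi - lo) for v in values]


def compute_terms(
    net: BipartiteCTNetwork,
    records: list[ComponentRecord],
    doses: list[HerbDose],
    herb_pair: tuple[str, str] | None = None,
    ecc_net: BipartiteCTNetwork | None = None,
) -> list[ContributionTerms]:
    """Assemble :class:`ContributionTerms` for every component of ``net``.

    ``herb_pair`` names the two herbs entering the asymmetry ratio; by
    default the two herbs found on the records (error if not exactly two).
    ``ecc_net`` optionally supplies a different network (e.g. the PPI-
    converged one) for eccentricity computation; degrees always come from
    the C-T network itself.
    """
    rec_by_id = {r.component_id: r for r in records}
    if herb_pair is None:
        herbs = sorted(set().union(*(r.herbs for r in records))) if records else []
        if len(herbs) != 2:
            raise ValueError(
                f"herb_pair must be given explicitly for {len(herbs)} herbs (need exactly 2)"
            )
        herb_pair = (herbs[0], herbs[1])
    scoring = ecc_net if ecc_net is not None else net
    eccs = all_eccentricities(scoring)
    ecc_a = all_eccentricities(herb_subnetwork(net, herb_pair[0]))
    ecc_b = all_eccentricities(herb_subnetwork(net, herb_pair[1]))

    out: list[ContributionTerms] = []
    for cid in net.components:
        rec = rec_by_id.get(cid)
        if rec is None:
            raise ValueError(f"network component {cid!r} has no record")
        targets = net.targets_of(cid)
        dose, mode = effective_dose(rec, doses)
        out.append(
            ContributionTerms(
                component_id=cid,
                comp_ecc=eccs[cid],
                comp_ecc_herb_a=ecc_a.get(cid, 0),
                comp_ecc_herb_b=ecc_b.get(cid, 0),
                c_edge=net.degree(cid),
                t_edge=sum(net.degree(t) for t in targets),
                target_eccs={t: eccs[t] for t in targets},
                dose=dose,
                dose_mode=mode,
            )
        )
    return out


def contribution_scores(
    terms: list[ContributionTerms], tar_mode: str = "per_target"
) -> list[ContributionScore]:
    """Score every component and rank descending.

    The C_ij normalization pool is global over all component–target pairs;
    the dose pool is over components.  Ties in CSC break by component id
    so the ranking (and any prefix of it) is deterministic.
    """
    if not terms:
        raise ValueError("no components to score")
    pairs: list[tuple[str, str]] = []
    raw: list[float] = []
    for t in terms:
        for tgt in sorted(t.target_eccs):
            pairs.append((t.component_id, tgt))
            raw.append(raw_edge_score(t, tgt, tar_mode=tar_mode))
    nl_dose = dict(
        zip((t.component_id for t in terms), minmax_normalize([t.dose for t in terms]))
    )
    nl_pair: dict[tuple[str, str], float] = {}
    if raw:
        nl_pair = dict(zip(pairs, minmax_normalize(raw)))

    csc: dict[str, float] = {}
    for t in terms:
        s = sum(nl_pair[(t.component_id, tgt)] + nl_dose[t.component_id]
                for tgt in t.target_eccs)
        csc[t.component_id] = s

    total = sum(csc.values())
    order = sorted(csc, key=lambda c: (-csc[c], c))
    scores: list[ContributionScore] = []
    cum = 0.0
    for rank, cid in enumerate(order, start=1):
        share = csc[cid] / total if total > 0 else 0.0
        cum += share
        scores.append(
            ContributionScore(component_id=cid, csc=csc[cid], rank=rank,
                              share=share, cumulative_share=min(cum, 1.0))
        )
    return scores


def select_functional_space(
    scores: list[ContributionScore],
    terms: list[ContributionTerms] | None = None,
    fraction: float = 0.90,
) -> FunctionalSpace:
    """Shortest ranking prefix whose cumulative CSC share reaches ``fraction``.

    When ``terms`` are supplied the union of the selected components'
    targets and its fraction of all targets are reported alongside.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not scores or sum(s.csc for s in scores) <= 0:
        raise ValueError("total contribution score is zero; ranking is degenerate")
    ranked = sorted(scores, key=lambda s: s.rank)
    selected: list[str] = []
    cum = 0.0
    for s in ranked:
        selected.append(s.component_id)
        cum += s.share
        if cum >= fraction - 1e-12:
            break
    covered: set[str] = set()
    all_targets: set[str] = set()
    if terms:
        by_id = {t.component_id: t for t in terms}
        for t in terms:
            all_targets.update(t.target_eccs)
        for cid in selected:
            covered.update(by_id[cid].target_eccs)
    return FunctionalSpace(
        component_ids=tuple(selected),
        achieved_share=min(cum, 1.0),
        fraction=fraction,
        covered_targets=frozenset(covered),
        coverage_fraction=(len(covered) / len(all_targets)) if all_targets else 0.0,
    )
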
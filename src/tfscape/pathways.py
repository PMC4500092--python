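"""Functional-complex criteria and evolutionary accessibility analysis.

A TF:RE complex is *functional* when (1) its mean ΔG_dissociation is
strictly greater than the grand mean over all complexes in the landscape
(moderate-to-high occupancy) and (2) its affinity constant is within a
given fold (default tenfold) of that protein's best target, i.e.
ΔG ≥ bestΔG(protein) − RT·ln(fold).  Both thresholds are recomputed from
the supplied landscape.

Two evolutionary scenarios are analysed on the resulting graph:

* protein trajectories — the 3! orderings of the three RH replacements,
  accessible when every intermediate protein (endpoints included) keeps
  at least one functional RE;
* joint neutral-network drift — paths through the graph of functional
  complexes connected by single protein replacements or single
  nucleotide changes, never losing function at any step.

Permissive/restrictive gating asks, for each functional complex, whether
taking one admissible move changes which other moves are admissible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .binding import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KCAL
from .genotype_space import (
    ANCSR1,
    PROTEIN_SITES,
    RESIDUES,
    JointGenotype,
    Move,
    ProteinGenotype,
    apply_move,
    available_moves,
    enumerate_joint_genotypes,
    enumerate_protein_genotypes,
    is_applicable,
    neighbors,
)

__all__ = [
    "FunctionalCriteria",
    "FunctionalCall",
    "FunctionalCalls",
    "PathReport",
    "GatingEvent",
    "GatingReport",
    "as_landscape",
    "classify_functional",
    "build_joint_graph",
    "protein_trajectories",
    "joint_paths",
    "gating_analysis",
]


@dataclass(frozen=True)
class FunctionalCriteria:
    """Two-part occupancy criterion for calling a complex functional."""

    fold: float = 10.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    R: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold factor must exceed 1")

    @property
    def fold_cutoff_kcal(self) -> float:
        """Energy margin below a protein's best target: RT·ln(fold)."""
        return self.R * self.temperature_K * math.log(self.fold)


@dataclass(frozen=True)
class FunctionalCall:
    genotype: JointGenotype
    functional: bool
    failed: str  # "none" | "below-mean" | "outside-fold" | "both"


def as_landscape(landscape) -> dict[JointGenotype, float]:
    """Coerce a landscape (dict or protein/re/mean_dG frame) to a dict."""
    if isinstance(landscape, dict):
        return {
            (g if isinstance(g, JointGenotype) else JointGenotype.from_label(g)): float(v)
            for g, v in landscape.items()
        }
    df = landscape
    return {
        JointGenotype.from_labels(p, r): float(v)
        for p, r, v in zip(df["protein"], df["re"], df["mean_dG"])
    }


@dataclass
class FunctionalCalls:
    """Per-complex functional classification over the full joint space."""

    calls: dict[JointGenotype, FunctionalCall]
    grand_mean: float
    best_targets: dict[ProteinGenotype, list[JointGenotype]]
    criteria: FunctionalCriteria

    def is_functional(self, genotype: JointGenotype) -> bool:
        return self.calls[genotype].functional

    def functional_set(self) -> set[JointGenotype]:
        return {g for g, c in self.calls.items() if c.functional}

    def functional_res(self, protein: ProteinGenotype) -> set[str]:
        return {
            g.re.label
            for g in self.functional_set()
            if g.protein == protein
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [g.protein.label for g in self.calls],
                "re": [g.re.label for g in self.calls],
                "functional": [c.functional for c in self.calls.values()],
                "failed": [c.failed for c in self.calls.values()],
            }
        )


def classify_functional(
    landscape, criteria: FunctionalCriteria = FunctionalCriteria()
) -> FunctionalCalls:
    """Apply both occupancy criteria to a complete 8 x 16 landscape."""
    values = as_landscape(landscape)
    missing = [g.label for g in enumerate_joint_genotypes() if g not in values]
    if missing:
        raise ValueError(f"incomplete landscape; missing cells: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    grand_mean = sum(values.values()) / len(values)
    best: dict[ProteinGenotype, list[JointGenotype]] = {}
    for p in enumerate_protein_genotypes():
        cells = {g: v for g, v in values.items() if g.protein == p}
        top = max(cells.values())
        best[p] = [g for g, v in cells.items() if v == top]
    calls = {}
    for g, v in values.items():
        above_mean = v > grand_mean
        cutoff = values[best[g.protein][0]] - criteria.fold_cutoff_kcal
        within_fold = v >= cutoff
        failed = {
            (True, True): "none",
            (False, True): "below-mean",
            (True, False): "outside-fold",
            (False, False): "both",
        }[(above_mean, within_fold)]
        calls[g] = FunctionalCall(g, above_mean and within_fold, failed)
    return FunctionalCalls(calls, grand_mean, best, criteria)


def build_joint_graph(calls: FunctionalCalls | set) -> nx.Graph:
    """Neutral network: functional complexes joined by single moves.

    Edges carry ``move_type`` (``protein`` or ``re``).  Accepts either a
    :class:`FunctionalCalls` or a bare set of functional genotypes.
    """
    functional = (
        calls.functional_set() if isinstance(calls, FunctionalCalls) else set(calls)
    )
    g = nx.Graph()
    g.add_nodes_from(x.label for x in functional)
    for node in functional:
        for nbr, move in neighbors(node):
            if nbr in functional:
                g.add_edge(node.label, nbr.label, move_type=move.molecule)
    return g


@dataclass
class PathReport:
    scenario: str
    source: str | None
    targets: list[str]
    connected: bool
    shortest_length: int | None
    paths: list[list[str]]
    orderings: list[dict] = field(default_factory=list)

    @property
    def n_accessible(self) -> int:
        return sum(1 for o in self.orderings if o["accessible"])


def protein_trajectories(
    landscape, criteria: FunctionalCriteria = FunctionalCriteria()
) -> PathReport:
    """Scenario 1: orderings of the three RH replacements from the
    all-ancestral to the all-derived protein.

    An ordering is accessible when every protein along it — endpoints
    included — has at least one functional RE.
    """
    calls = classify_functional(landscape, criteria)
    orderings = []
    for order in itertools.permutations(PROTEIN_SITES):
        flags = [False, False, False]
        steps = []
        accessible = True
        proteins = [ProteinGenotype(*flags)]
        for site in order:
            flags[PROTEIN_SITES.index(site)] = True
            proteins.append(ProteinGenotype(*flags))
        for p in proteins:
            res = sorted(calls.functional_res(p))
            steps.append({"protein": p.label, "functional_res": res})
            if not res:
                accessible = False
        orderings.append(
            {
                "order": [f"{RESIDUES[s][0]}{s}{RESIDUES[s][1]}" for s in order],
                "accessible": accessible,
                "steps": steps,
            }
        )
    return PathReport(
        scenario="protein_trajectories",
        source=ANCSR1.label,
        targets=[ProteinGenotype(True, True, True).label],
        connected=any(o["accessible"] for o in orderings),
        shortest_length=3 if any(o["accessible"] for o in orderings) else None,
        paths=[],
        orderings=orderings,
    )


def joint_paths(
    graph: nx.Graph,
    source,
    targets,
    path_cap: int = 10_000,
) -> PathReport:
    """Scenario 2: breadth-first accessibility through the neutral network.

    Connectivity is exact; shortest paths are enumerated up to
    ``path_cap``.  The source must be a functional node of the graph.
    """
    src = source.label if isinstance(source, JointGenotype) else str(source)
    tgt = [
        t.label if isinstance(t, JointGenotype) else str(t) for t in targets
    ]
    if src not in graph:
        raise ValueError(f"source {src!r} is not a functional complex")
    if src in tgt:
        return PathReport("joint_paths", src, tgt, True, 0, [[src]])
    lengths = nx.single_source_shortest_path_length(graph, src)
    reachable = [t for t in tgt if t in lengths]
    if not reachable:
        return PathReport("joint_paths", src, tgt, False, None, [])
    best = min(lengths[t] for t in reachable)
    paths: list[list[str]] = []
    for t in reachable:
        if lengths[t] != best:
            continue
        for p in nx.all_shortest_paths(graph, src, t):
            paths.append(list(p))
            if len(paths) >= path_cap:
                break
        if len(paths) >= path_cap:
            break
    return PathReport("joint_paths", src, tgt, True, best, paths)


@dataclass(frozen=True)
class GatingEvent:
    """One permissive or restrictive interaction between moves.

    At context node ``g``: taking admissible move ``gating_move`` makes
    ``focal_move`` admissible where it was not (permissive) or
    inadmissible where it was (restrictive)."""

    context: str
    gating_move: str
    focal_move: str
    kind: str  # "permissive" | "restrictive"
    cross_molecule: bool


@dataclass
class GatingReport:
    events: list[GatingEvent]

    def cross_molecule_events(self) -> list[GatingEvent]:
        return [e for e in self.events if e.cross_molecule]

    def permissive(self) -> list[GatingEvent]:
        return [e for e in self.events if e.kind == "permissive"]

    def restrictive(self) -> list[GatingEvent]:
        return [e for e in self.events if e.kind == "restrictive"]


def _admissible(move: Move, genotype: JointGenotype, functional: set) -> bool:
    return is_applicable(move, genotype) and apply_move(move, genotype) in functional


def gating_analysis(
    landscape,
    criteria: FunctionalCriteria = FunctionalCriteria(),
    context=None,
) -> GatingReport:
    """Enumerate permissive and restrictive move interactions.

    For every functional node g, every admissible move m from g and every
    other move m′ applicable both before and after m: m is permissive for
    m′ when m′ is inadmissible at g but admissible at g∘m, and restrictive
    in the converse case.  ``context`` optionally restricts the nodes
    examined.
    """
    calls = classify_functional(landscape, criteria)
    functional = calls.functional_set()
    if context is not None:
        wanted = {
            c.label if isinstance(c, JointGenotype) else str(c) for c in context
        }
        nodes = [g for g in functional if g.label in wanted]
    else:
        nodes = sorted(functional, key=lambda g: g.label)
    events = []
    for g in nodes:
        for m in available_moves(g):
            if not _admissible(m, g, functional):
                continue
            after = apply_move(m, g)
            for mprime in available_moves(g):
                if mprime == m:
                    continue
                if not is_applicable(mprime, after):
                    continue
                before_ok = _admissible(mprime, g, functional)
                after_ok = _admissible(mprime, after, functional)
                if before_ok == after_ok:
                    continue
                events.append(
                    GatingEvent(
                        context=g.label,
                        gating_move=m.label,
                        focal_move=mprime.label,
                        kind="permissive" if after_ok else "restrictive",
                        cross_molecule=m.molecule != mprime.molecule,
                    )
                )
    return GatingReport(events)
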
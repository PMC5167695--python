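"""Cross-experiment alignment of signal areas into consensus transcripts.

Signal areas called independently in several experiments at the same locus
are reconciled by building an overlap graph: nodes are the areas, edges
connect areas on the same replicon and strand whose intervals share at
least one base.  Each connected component becomes one consensus transcript
whose boundaries are the signal-weighted average of the member boundaries,

    <x> = sum_i p_i x_i,   p_i = |Mbar_i| / sum_j |Mbar_j|,

so areas with stronger pseudomedian signal pull the consensus harder.  An
optional pre-filter discards areas whose |pseudomedian M| falls below a
noise floor before the graph is built.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .segmentation import SignalArea, pseudomedian
from .signal_io import _round_half_away

logger = logging.getLogger("chipsad")


@dataclass
class SASGraph:
    graph: nx.Graph
    components: list[list[SignalArea]]


@dataclass
class ConsensusSAS:
    """A weighted merge of overlapping signal areas from several experiments."""

    replicon: str
    strand: str
    start: int
    end: int
    members: list[SignalArea] = field(repr=False)
    per_experiment_M: dict[str, float]
    weights: np.ndarray = field(repr=False)

    @property
    def M(self) -> float:
        """Overall intensity: pseudomedian of the per-experiment values."""
        return pseudomedian(list(self.per_experiment_M.values()))

    # alias so the shared writers treat consensus and plain areas alike
    @property
    def pseudomedian_M(self) -> float:
        return self.M

    @property
    def transcript_id(self) -> str:
        return f"{self.replicon}:{self.start}-{self.end}({self.strand})"


def filter_by_pseudomedian(sas_list, min_abs_M: float = 0.0):
    """Drop areas with |pseudomedian M| below the noise floor (0 = keep all)."""
    if min_abs_M <= 0:
        return list(sas_list)
    return [s for s in sas_list if abs(s.pseudomedian_M) >= min_abs_M]


def build_overlap_graph(sas_by_experiment: dict[str, list[SignalArea]]) -> SASGraph:
    """Connect same-replicon, same-strand areas that overlap by >= 1 bp.

    Intervals are 1-based inclusive, so adjacency (end + 1 == start) is not
    overlap.  Connected components are the loci to be merged.
    """
    g: nx.Graph = nx.Graph()
    nodes: list[SignalArea] = []
    for exp in sorted(sas_by_experiment):
        for sas in sas_by_experiment[exp]:
            g.add_node(len(nodes))
            nodes.append(sas)

    by_group: dict[tuple[str, str], list[int]] = {}
    for i, sas in enumerate(nodes):
        by_group.setdefault((sas.replicon, sas.strand), []).append(i)
    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: nodes[i].start)
        active: list[int] = []
        for i in idxs:
            s = nodes[i]
            active = [j for j in active if nodes[j].end >= s.start]
            for j in active:
                g.add_edge(i, j)
            active.append(i)

    components = [
        sorted((nodes[i] for i in comp), key=lambda s: (s.experiment_id, s.start))
        for comp in nx.connected_components(g)
    ]
    components.sort(key=lambda c: (c[0].replicon, c[0].strand, min(s.start for s in c)))
    return SASGraph(graph=g, components=components)


def _experiment_M(members: list[SignalArea]) -> float:
    """Summary M for one experiment's members of a component.

    A single member contributes its own pseudomedian; several members from
    the same experiment are summarized by the pseudomedian of the union of
    their probe values (falling back to the pseudomedian of their area
    values when probe-level data is unavailable, e.g. after a file round
    trip).
    """
    if len(members) == 1:
        return members[0].pseudomedian_M
    if all(m.probe_Ms is not None and len(m.probe_Ms) for m in members):
        return pseudomedian(np.concatenate([m.probe_Ms for m in members]))
    return pseudomedian([m.pseudomedian_M for m in members])


def consensus_boundaries(component: list[SignalArea]) -> ConsensusSAS:
    """Signal-weighted consensus boundaries for one connected component.

    Weights are p_i = |Mbar_i| / sum |Mbar_j|; when every member has zero
    pseudomedian the weights fall back to uniform (logged).  Boundaries are
    rounded to the nearest base, half away from zero, and always lie within
    the convex hull of the member boundaries.
    """
    if not component:
        raise ValueError("empty component")
    replicons = {s.replicon for s in component}
    strands = {s.strand for s in component}
    if len(replicons) != 1 or len(strands) != 1:
        raise ValueError("component mixes replicons or strands")

    abs_m = np.array([abs(s.pseudomedian_M) for s in component])
    total = float(abs_m.sum())
    if total == 0:
        logger.warning(
            "component at %s:%d has all-zero pseudomedians; uniform weights",
            component[0].replicon, component[0].start,
        )
        weights = np.full(len(component), 1.0 / len(component))
    else:
        weights = abs_m / total

    starts = np.array([s.start for s in component], dtype=float)
    ends = np.array([s.end for s in component], dtype=float)
    start = _round_half_away(float(weights @ starts))
    end = _round_half_away(float(weights @ ends))

    per_exp: dict[str, list[SignalArea]] = {}
    for s in component:
        per_exp.setdefault(s.experiment_id, []).append(s)
    per_experiment_M = {exp: _experiment_M(ms) for exp, ms in sorted(per_exp.items())}

    return ConsensusSAS(
        replicon=component[0].replicon,
        strand=component[0].strand,
        start=start,
        end=end,
        members=list(component),
        per_experiment_M=per_experiment_M,
        weights=weights,
    )


def align_experiments(
    sas_by_experiment: dict[str, list[SignalArea]], min_abs_M: float = 0.0
) -> list[ConsensusSAS]:
    """Filter, build the overlap graph, and emit one consensus per component."""
    filtered = {
        exp: filter_by_pseudomedian(sas_list, min_abs_M)
        for exp, sas_list in sas_by_experiment.items()
    }
    graph = build_overlap_graph(filtered)
    out = [consensus_boundaries(c) for c in graph.components]
    out.sort(key=lambda c: (c.replicon, c.strand, c.start, c.end))
    logger.info(
        "aligned %d experiments: %d areas -> %d consensus transcripts",
        len(filtered), sum(len(v) for v in filtered.values()), len(out),
    )
    return out


def expression_matrix(consensus_list: list[ConsensusSAS]) -> pd.DataFrame:
    """Experiment x transcript matrix of per-experiment pseudomedian M.

    Rows are transcripts, columns experiments; an experiment absent from a
    component is NaN (missing, not "no change").
    """
    experiments = sorted({e for c in consensus_list for e in c.per_experiment_M})
    rows = {
        c.transcript_id: {e: c.per_experiment_M.get(e, math.nan) for e in experiments}
        for c in consensus_list
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=experiments)


def select_differential(
    consensus_list: list[ConsensusSAS],
    experiments_of_interest: list[str],
    min_fold_change: float = 2.0,
) -> tuple[list[ConsensusSAS], pd.DataFrame]:
    """Keep transcripts with |M| >= log2(fold change) in every named experiment.

    Returns the surviving consensus transcripts plus the full expression
    matrix (all transcripts), suitable for heat-map style output.
    """
    if min_fold_change < 1:
        raise ValueError("min_fold_change must be >= 1")
    known = {e for c in consensus_list for e in c.per_experiment_M}
    for exp in experiments_of_interest:
        if exp not in known:
            raise ValueError(f"experiment {exp!r} absent from every transcript")
    threshold = math.log2(min_fold_change)
    kept = [
        c
        for c in consensus_list
        if all(
            exp in c.per_experiment_M and abs(c.per_experiment_M[exp]) >= threshold
            for exp in experiments_of_interest
        )
    ]
    return kept, expression_matrix(consensus_list)
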
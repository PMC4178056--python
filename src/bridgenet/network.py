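"""Construction of the constrained, weighted, directed sensor-enzyme network.

The reference ("bridge") network is built in four stages: integrate PPI and
PDI records into one directed graph; weight edges by co-expression distance
d = 1 - r^2; drop nodes with low target-tissue expression; and restrict to
sensors, enzymes and the intermediates lying on some directed sensor->enzyme
walk.  Each stage is a pure function returning a new :class:`BridgeNetwork`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, InteractionKind, InteractionRecord

logger = logging.getLogger(__name__)

ROLES = ("sensor", "enzyme", "intermediate")


class ConstructionError(ValueError):
    """A network-construction precondition failed."""


@dataclass
class BridgeNetwork:
    """Directed weighted graph with node roles and edge distances in [0, 1].

    Node attribute ``role`` is one of ``sensor`` / ``enzyme`` /
    ``intermediate`` (or unset before role assignment).  Edge attributes are
    ``kind`` (``PPI``/``PDI``) and ``distance``.  Every PPI contributes two
    antiparallel directed edges with equal distance; every PDI exactly one
    TF -> target edge.
    """

    graph: nx.DiGraph
    provenance: dict = field(default_factory=dict)

    def role(self, node: str) -> str | None:
        return self.graph.nodes[node].get("role")

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("role") == role}

    @property
    def sensors(self) -> set[str]:
        return self.nodes_with_role("sensor")

    @property
    def enzymes(self) -> set[str]:
        return self.nodes_with_role("enzyme")

    @property
    def intermediates(self) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True)
            if d.get("role", "intermediate") == "intermediate"
        }

    def copy(self) -> "BridgeNetwork":
        return BridgeNetwork(self.graph.copy(), dict(self.provenance))

    def set_roles(self, sensors: Iterable[str], enzymes: Iterable[str]) -> None:
        """Assign node roles in place; a gene listed as both becomes enzyme (logged)."""
        sensors = {s.upper() for s in sensors}
        enzymes = {t.upper() for t in enzymes}
        overlap = sensors & enzymes
        if overlap:
            logger.warning("genes listed as both sensor and enzyme assigned enzyme: %s",
                           sorted(overlap))
        for n in self.graph.nodes:
            if n in enzymes:
                role = "enzyme"
            elif n in sensors:
                role = "sensor"
            else:
                role = "intermediate"
            self.graph.nodes[n]["role"] = role


def integrate_interactions(
    ppi: Sequence[InteractionRecord], pdi: Sequence[InteractionRecord]
) -> BridgeNetwork:
    """Merge PPI and PDI records into one directed graph (roles unset).

    Self-loops are dropped.  Each PPI yields two antiparallel edges; each PDI
    a single TF->target edge.  Duplicate directed edges collapse into one,
    labelled PDI if any contributing record was a PDI (kind priority
    PDI > PPI), since the protein-DNA evidence fixes the direction semantics.
    """
    g = nx.DiGraph()
    n_loops = 0
    for rec in list(ppi) + list(pdi):
        if rec.source == rec.target:
            n_loops += 1
            continue
        directed_pairs = [(rec.source, rec.target)]
        if rec.kind is InteractionKind.PPI:
            directed_pairs.append((rec.target, rec.source))
        for u, v in directed_pairs:
            if g.has_edge(u, v):
                if rec.kind is InteractionKind.PDI:
                    g[u][v]["kind"] = "PDI"
            else:
                g.add_edge(u, v, kind=rec.kind.value, distance=1.0)
    if n_loops:
        logger.info("dropped %d self-loop interactions", n_loops)
    return BridgeNetwork(g, {"n_ppi": len(ppi), "n_pdi": len(pdi)})


def coexpression_distance(r: float) -> float:
    """Co-expression distance d = 1 - r^2 for a correlation coefficient r.

    Symmetric in the sign of r; perfectly (anti)correlated pairs are at
    distance 0 and uncorrelated pairs at distance 1.
    """
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"correlation coefficient out of [-1, 1]: {r}")
    return float(1.0 - min(abs(r), 1.0) ** 2)


def assign_edge_distances(network: BridgeNetwork, expr: ExpressionMatrix) -> BridgeNetwork:
    """Weight every edge by d = 1 - r^2, r the Pearson correlation of its endpoints.

    Edges whose endpoints are absent from the expression matrix, or whose
    correlation is undefined (zero variance), get the maximal distance 1 and
    are logged — such pairs are penalized rather than dropped.
    """
    out = network.copy()
    values = expr.values
    n_fallback = 0
    # row lookup once; correlations use pairwise-complete observations
    for u, v, d in out.graph.edges(data=True):
        if u not in values.index or v not in values.index:
            d["distance"] = 1.0
            n_fallback += 1
            continue
        x = values.loc[u].to_numpy(dtype=float)
        y = values.loc[v].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            d["distance"] = 1.0
            n_fallback += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        d["distance"] = coexpression_distance(r)
    if n_fallback:
        logger.warning(
            "%d of %d edges got fallback distance 1 (endpoint missing or zero variance)",
            n_fallback, out.graph.number_of_edges(),
        )
    out.provenance["coexpression_samples"] = len(expr.samples)
    return out


@dataclass
class TissuePanel:
    """Gene x tissue-sample expression with the target-tissue columns marked."""

    values: pd.DataFrame
    target_samples: list[str]

    def __post_init__(self) -> None:
        missing = [s for s in self.target_samples if s not in self.values.columns]
        if not self.target_samples or missing:
            raise ValueError(f"target-tissue samples missing from panel: {missing or 'none given'}")

    def expression_ratio(self) -> pd.Series:
        """Per-gene ratio of target-tissue mean to panel-wide mean expression."""
        target = self.values[self.target_samples].mean(axis=1)
        overall = self.values.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return target / overall


def filter_by_tissue_expression(
    network: BridgeNetwork,
    panel: TissuePanel,
    percentile_cutoff: float = 40.0,
    exempt: Iterable[str] | None = None,
) -> BridgeNetwork:
    """Remove nodes whose target-tissue/panel-wide expression ratio is low.

    The threshold is the ``percentile_cutoff``-th percentile of the ratio
    distribution over genes present in both panel and network, so the cutoff
    adapts to the analyzed universe.  Sensor and enzyme nodes (or an explicit
    ``exempt`` set) are never removed; genes absent from the panel are
    retained and logged.
    """
    if not 0 <= percentile_cutoff <= 100:
        raise ValueError("percentile_cutoff must be in [0, 100]")
    if panel.values.empty:
        raise ConstructionError("empty tissue panel")
    out = network.copy()
    exempt_set = {g.upper() for g in exempt} if exempt is not None else (
        out.sensors | out.enzymes
    )
    ratios = panel.expression_ratio()
    in_both = [n for n in out.graph.nodes if n in ratios.index]
    absent = [n for n in out.graph.nodes if n not in ratios.index]
    if absent:
        logger.info("%d network genes absent from tissue panel retained", len(absent))
    if not in_both:
        return out
    universe = ratios.loc[in_both]
    threshold = float(np.percentile(universe.to_numpy(dtype=float), percentile_cutoff))
    to_remove = [
        n for n in in_both if universe[n] < threshold and n not in exempt_set
    ]
    out.graph.remove_nodes_from(to_remove)
    out.provenance["tissue_percentile_cutoff"] = percentile_cutoff
    out.provenance["tissue_filter_removed"] = len(to_remove)
    return out


def extract_reference_network(
    network: BridgeNetwork, sensors: Iterable[str], enzymes: Iterable[str]
) -> BridgeNetwork:
    """Restrict to sensors, enzymes and intermediates on some sensor->enzyme walk.

    A node i is retained iff it is a sensor or enzyme, or there exist a sensor
    s and enzyme t with finite directed distances d(s, i) and d(i, t).
    Reachability follows edge direction throughout (PDIs are one-way).
    Idempotent; with sensors = enzymes = all nodes this is the identity.
    """
    sensors = {s.upper() for s in sensors}
    enzymes = {t.upper() for t in enzymes}
    out = network.copy()
    g = out.graph
    present_s = sensors & set(g.nodes)
    present_t = enzymes & set(g.nodes)
    for label, given, present in (("sensor", sensors, present_s), ("enzyme", enzymes, present_t)):
        missing = given - present
        if missing:
            logger.warning("%s genes not in network: %s", label, sorted(missing))
        if not present:
            raise ConstructionError(f"no {label} gene present in the network")
    out.set_roles(present_s, present_t)
    # forward reachability from any sensor, backward from any enzyme
    from_sensors: set[str] = set(present_s)
    for s in present_s:
        from_sensors |= nx.descendants(g, s)
    to_enzymes: set[str] = set(present_t)
    for t in present_t:
        to_enzymes |= nx.ancestors(g, t)
    keep = (from_sensors & to_enzymes) | present_s | present_t
    g.remove_nodes_from([n for n in list(g.nodes) if n not in keep])
    out.provenance["sensors"] = sorted(present_s)
    out.provenance["enzymes"] = sorted(present_t)
    return out
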
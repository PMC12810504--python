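"""Node-removal fragility analysis: remove designated hub genes one at a
time, recompute the topology panel, and report the deltas.

Each removal is applied independently to the original network (not
cumulatively), so every per-removal panel has exactly one node fewer than
the baseline and loses exactly the removed node's incident edges.  Loss of
communication efficiency shows up as growth in diameter and characteristic
path length; loss of cohesion as drops in clustering coefficient and
density.  If a removal disconnects the network, the distance statistics
follow the connected-pairs convention of :mod:`netpharm.graph_core` and the
panel's ``n_components`` flags the fragmentation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .graph_core import (InteractionNetwork, MetricPanel, PANEL_METRICS,
                         metric_panel)

__all__ = ["FragilityReport", "remove_node", "fragility_analysis"]


@dataclass
class FragilityReport:
    """Baseline panel, one panel per removed hub, and per-metric deltas."""

    baseline: MetricPanel
    removals: dict[str, MetricPanel]
    deltas: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self, ndigits: int | None = 3) -> pd.DataFrame:
        """Metrics-by-columns table: baseline first, then each removal."""
        cols = {"original": self.baseline.to_dict(ndigits)}
        for gene, panel in self.removals.items():
            cols[f"no_{gene}"] = panel.to_dict(ndigits)
        frame = pd.DataFrame(cols)
        return frame.loc[[m for m in PANEL_METRICS + ["n_components"]
                          if m in frame.index]]


def remove_node(net: InteractionNetwork, gene: str) -> InteractionNetwork:
    """A copy of the network without ``gene`` and its incident edges."""
    if gene not in net.nodes:
        raise ValidationError(f"cannot remove unknown gene {gene!r}")
    g = net.graph.copy()
    g.remove_node(gene)
    return InteractionNetwork(g)


def fragility_analysis(
    net: InteractionNetwork,
    hubs: list[str],
) -> FragilityReport:
    """Independent single-node removals of each hub, with recomputed panels.

    The hub order is reporting order only; it does not affect any panel.
    """
    if len(set(hubs)) != len(hubs):
        raise ValidationError("duplicate gene in hub removal list")
    missing = [h for h in hubs if h not in net.nodes]
    if missing:
        raise ValidationError(f"hub gene(s) not in network: {missing}")
    baseline = metric_panel(net)
    removals: dict[str, MetricPanel] = {}
    deltas: dict[str, dict[str, float]] = {}
    base = baseline.to_dict()
    for gene in hubs:
        panel = metric_panel(remove_node(net, gene))
        removals[gene] = panel
        deltas[gene] = {m: panel.to_dict()[m] - base[m] for m in PANEL_METRICS}
    return FragilityReport(baseline=baseline, removals=removals, deltas=deltas)
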
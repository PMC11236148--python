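"""Zi-Pi node-role analysis and keystone classification.

Within-module degree z-score::

    Zi = (K_i - mean(K, over i's module)) / sd(K, over i's module)

where K_i counts node i's links to members of its own module, and the mean
and standard deviation run over the within-module degrees of all nodes in
that module (population SD).

Participation coefficient::

    Pi = 1 - sum_s (K_is / k_i)^2

where K_is counts node i's links into module s and k_i is its **total**
degree (Guimera-Amaral convention).

Roles: peripheral (Zi <= 2.5, Pi <= 0.62), connector (Zi <= 2.5, Pi > 0.62),
module hub (Zi > 2.5, Pi <= 0.62), network hub (Zi > 2.5, Pi > 0.62);
boundary-equal values fall in the lower category. Connectors and hubs are
the keystone candidates: their loss is predicted to fragment the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CooccurrenceNetwork, detect_modules
from .tables import ValidationError

__all__ = ["NodeRole", "zi_pi", "classify_keystones", "ZI_THRESHOLD", "PI_THRESHOLD"]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class NodeRole:
    node: str
    module: int
    zi: float
    pi: float
    role: str  # peripheral | connector | module_hub | network_hub


def _role(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD:
        return "network_hub" if pi > PI_THRESHOLD else "module_hub"
    return "connector" if pi > PI_THRESHOLD else "peripheral"


def zi_pi(net: CooccurrenceNetwork) -> list[NodeRole]:
    """Compute Zi, Pi and the topological role for every node.

    Detects modules first if the network has no stored partition. Degenerate
    cases: a module whose within-module degrees have zero spread gives its
    members Zi = 0; an isolated node gets Pi = 0 with a warning.
    """
    g = net.graph
    if net.partition is None:
        detect_modules(net)
    part = net.partition
    nodes = list(g.nodes)
    if set(part) != set(nodes):
        raise ValidationError("module partition does not cover all nodes")

    within = {
        v: sum(1 for u in g.neighbors(v) if part[u] == part[v]) for v in nodes
    }
    by_module: dict[int, list[str]] = {}
    for v in nodes:
        by_module.setdefault(part[v], []).append(v)
    stats_by_module = {
        mid: (
            float(np.mean([within[v] for v in members])),
            float(np.std([within[v] for v in members])),
        )
        for mid, members in by_module.items()
    }

    roles = []
    for v in nodes:
        mu, sd = stats_by_module[part[v]]
        zi = (within[v] - mu) / sd if sd > 0 else 0.0
        k = g.degree(v)
        if k == 0:
            warnings.warn(f"node {v!r} has degree 0; Pi set to 0", stacklevel=2)
            pi = 0.0
        else:
            into = {}
            for u in g.neighbors(v):
                into[part[u]] = into.get(part[u], 0) + 1
            pi = 1.0 - sum((kis / k) ** 2 for kis in into.values())
        roles.append(NodeRole(node=v, module=part[v], zi=zi, pi=pi, role=_role(zi, pi)))
    return roles


def classify_keystones(roles: list[NodeRole]) -> list[NodeRole]:
    """Non-peripheral nodes (connectors, module hubs, network hubs), sorted
    by role then by Zi + Pi descending."""
    order = {"network_hub": 0, "module_hub": 1, "connector": 2}
    keys = [r for r in roles if r.role != "peripheral"]
    return sorted(keys, key=lambda r: (order[r.role], -(r.zi + r.pi), r.node))


def roles_table(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"node": r.node, "module": r.module, "Zi": r.zi, "Pi": r.pi, "role": r.role}
            for r in roles
        ]
    )
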
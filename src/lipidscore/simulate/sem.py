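"""Mixed-type structural equation model sampler over a known DAG."""

from __future__ import annotations

from typing import Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .config import PlantedTruth, SEMConfig

__all__ = ["generate_sem"]


class CycleError(ValueError):
    """Raised when the configured edge set is not acyclic."""


def generate_sem(cfg: SEMConfig, seed: int) -> Tuple[pd.DataFrame, PlantedTruth]:
    """Simulate ``cfg.n`` rows from the configured DAG.

    Continuous children are linear-Gaussian in their parents; binary children
    follow a logistic link.  Variables are simulated in topological order.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    types = dict(cfg.variables)

    g = nx.DiGraph()
    g.add_nodes_from(types)
    for u, v, w in cfg.edges:
        g.add_edge(u, v, weight=w)
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError("SEM edge set contains a cycle")

    data = {}
    for node in nx.topological_sort(g):
        parents = list(g.predecessors(node))
        lin = np.full(cfg.n, cfg.intercepts.get(node, 0.0))
        for par in parents:
            lin = lin + g[par][node]["weight"] * data[par]
        if types[node] == "continuous":
            sd = cfg.noise_sd.get(node, 1.0)
            data[node] = lin + rng.normal(0.0, sd, size=cfg.n)
        else:
            prob = 1.0 / (1.0 + np.exp(-lin))
            data[node] = (rng.random(cfg.n) < prob).astype(float)

    df = pd.DataFrame({name: data[name] for name, _ in cfg.variables})
    truth = PlantedTruth(dag_edges=[(u, v, float(w)) for u, v, w in cfg.edges])
    return df, truth
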
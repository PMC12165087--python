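"""Locus-level haplotype classes, frequency tables and a minimum-spanning
haplotype network.

The network is a minimum spanning tree over pairwise Hamming distances plus
every alternative edge of equal weight to the MST edge it could replace
(a minimum-spanning network); median-joining inference of unobserved
haplotypes is deliberately not implemented.  Haplogroups are the two
components obtained by removing the single largest-weight MST edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ArgumentError, MappingError
from .genio import MISSING, HaplotypePanel, PopulationMap

logger = logging.getLogger(__name__)

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ArgumentError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass
class HaplotypeClass:
    label: str
    allele_string: str
    members: list[tuple[str, int]]  # (sample, haplotype index)
    count_per_population: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.members)


def extract_haplotypes(
    panel: HaplotypePanel,
    region: tuple[int, int] | None = None,
    maf_min: float = 0.05,
    popmap: PopulationMap | None = None,
) -> list[HaplotypeClass]:
    """Collapse the haplotypes of a region into classes.

    Sites are filtered to MAF > ``maf_min`` over the panel's samples;
    haplotypes with missing alleles at any retained site are excluded (with
    a logged count).  Classes are labelled with roman numerals in
    (count desc, allele string asc) order.
    """
    if not panel.phased:
        raise ArgumentError("haplotype extraction requires a phased panel")
    sub = panel.region(*region) if region is not None else panel
    a = sub.alleles
    called = a != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called, a, 0).sum(axis=0) / np.maximum(n_called, 1)
    maf = np.minimum(freq, 1 - freq)
    keep = (n_called > 0) & (maf > maf_min)
    if not keep.any():
        logger.warning("extract_haplotypes: no site passes the MAF filter")
        return []
    a = a[:, keep]
    labels = sub.haplotype_labels()
    classes: dict[str, list[tuple[str, int]]] = {}
    n_dropped = 0
    for row, who in zip(a, labels):
        if (row == MISSING).any():
            n_dropped += 1
            continue
        key = "".join(str(int(x)) for x in row)
        classes.setdefault(key, []).append(who)
    if n_dropped:
        logger.info("extract_haplotypes: %d haplotypes dropped for missing data", n_dropped)
    ordered = sorted(classes.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out = [
        HaplotypeClass(label=roman(i + 1), allele_string=key, members=members)
        for i, (key, members) in enumerate(ordered)
    ]
    if popmap is not None:
        for cls in out:
            counts: dict[str, int] = {}
            for sample, _ in cls.members:
                counts[popmap.population_of(sample)] = (
                    counts.get(popmap.population_of(sample), 0) + 1
                )
            cls.count_per_population = counts
    return out


def hap_frequency_table(
    classes: list[HaplotypeClass], popmap: PopulationMap
) -> pd.DataFrame:
    """(class x population) counts and within-population proportions."""
    pops: list[str] = []
    for cls in classes:
        for sample, _ in cls.members:
            pop = popmap.population_of(sample)
            if pop not in pops:
                pops.append(pop)
    totals = {
        pop: sum(
            1
            for cls in classes
            for sample, _ in cls.members
            if popmap.population_of(sample) == pop
        )
        for pop in pops
    }
    rows = []
    for cls in classes:
        counts = {pop: 0 for pop in pops}
        for sample, _ in cls.members:
            counts[popmap.population_of(sample)] += 1
        for pop in pops:
            rows.append(
                (
                    cls.label,
                    pop,
                    counts[pop],
                    totals[pop],
                    counts[pop] / totals[pop] if totals[pop] else float("nan"),
                )
            )
        cls.count_per_population = {p: c for p, c in counts.items() if c}
    return pd.DataFrame(
        rows, columns=["haplotype", "population", "count", "pop_total", "proportion"]
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ArgumentError("allele strings differ in length")
    return sum(x != y for x, y in zip(a, b))


def build_network(classes: list[HaplotypeClass]) -> nx.Graph:
    """Minimum-spanning haplotype network.

    Nodes are class labels (attributes ``count``, ``allele_string``); MST
    edges carry ``is_alternative=False``; every non-tree edge whose weight
    equals the largest weight on the MST path between its endpoints is added
    with ``is_alternative=True``.  Deterministic under the lexicographic
    (weight, labels) edge order.
    """
    g = nx.Graph()
    for cls in classes:
        g.add_node(cls.label, count=cls.count, allele_string=cls.allele_string)
    if len(classes) < 2:
        return g
    edges = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            edges.append(
                (
                    hamming(classes[i].allele_string, classes[j].allele_string),
                    classes[i].label,
                    classes[j].label,
                )
            )
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    # Kruskal
    parent = {cls.label: cls.label for cls in classes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.append((w, u, v))
            g.add_edge(u, v, weight=w, is_alternative=False)
    tree = nx.Graph((u, v, {"weight": w}) for w, u, v in mst)
    for w, u, v in edges:
        if g.has_edge(u, v):
            continue
        path = nx.shortest_path(tree, u, v)
        max_on_path = max(
            tree[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        if w == max_on_path:
            g.add_edge(u, v, weight=w, is_alternative=True)
    return g


def haplogroups(network: nx.Graph) -> dict[str, str]:
    """Bipartition node labels into haplogroups 'A'/'B' by removing the
    largest-weight MST edge (ties break lexicographically)."""
    tree_edges = [
        (d["weight"], u, v)
        for u, v, d in network.edges(data=True)
        if not d["is_alternative"]
    ]
    if not tree_edges:
        return {n: "A" for n in network.nodes}
    tree = nx.Graph((u, v) for _, u, v in tree_edges)
    w_max, u_cut, v_cut = max(tree_edges, key=lambda e: (e[0], e[1], e[2]))
    tree.remove_edge(u_cut, v_cut)
    comp_u = nx.node_connected_component(tree, u_cut)
    side_a = comp_u if min(comp_u) == min(n for n in tree.nodes) else set(tree.nodes) - comp_u
    return {n: ("A" if n in side_a else "B") for n in tree.nodes}


def network_edge_table(network: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (u, v, d["weight"], d["is_alternative"])
            for u, v, d in sorted(network.edges(data=True))
        ],
        columns=["node_a", "node_b", "hamming", "is_alternative"],
    )
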
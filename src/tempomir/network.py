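"""Knowledgebase networks: greedy construction, Fisher scoring, growth,
merging, hubs, enrichment.

From each paired dataset, "network-eligible" molecules (dataset members
present in the knowledgebase graph) seed fixed-size (35-molecule)
connected networks built greedily for connectivity.  Each network is
scored as -log10 of the right-tailed Fisher exact (hypergeometric)
p-value for the enrichment of dataset ("focus") molecules among its
members, relative to the knowledgebase universe, and ranked by score.
Networks from different datasets are compared to call hub molecules
(top within-network degree in >= 2 datasets); the top-3 networks of the
0h- and 8h-miRNA datasets are merged — expanding gene families to all
dataset members — to call critical network genes (120 h DE genes common
to both merged networks).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

NETWORK_SIZE = 35
N_NETWORKS = 3
GROW_N = 10
HUB_TOP_K = 3


@dataclass
class Network:
    """A connected molecule set on the knowledgebase graph."""

    molecules: list[str]
    focus: set[str]
    source_dataset: str = ""
    score: float = 0.0
    rank: int = 0

    def __post_init__(self) -> None:
        if len(self.molecules) != len(set(self.molecules)):
            raise ValueError("duplicate molecules in network")
        if not self.focus <= set(self.molecules):
            raise ValueError("focus must be a subset of the network's molecules")

    def degrees(self, kb: nx.Graph) -> dict[str, int]:
        sub = kb.subgraph(self.molecules)
        return {m: sub.degree(m) for m in self.molecules}


def inject_interaction_edges(kb: nx.Graph, pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Add miRNA->target edges from the interaction table to the graph.

    miRNAs only appear in networks through these edges; molecules absent
    from the knowledgebase are added as typed nodes.
    """
    g = kb.copy()
    for m, t in pairs:
        if m not in g:
            g.add_node(m, type="mirna", family_id="")
        if t not in g:
            g.add_node(t, type="gene", family_id="")
        if m != t:
            g.add_edge(m, t)
    return g


def _edges_into(g: nx.Graph, node: str, members: set[str]) -> int:
    return sum(1 for nb in g.neighbors(node) if nb in members)


def build_networks(
    dataset_molecules: Iterable[str],
    kb: nx.Graph,
    size: int = NETWORK_SIZE,
    n_networks: int = N_NETWORKS,
    dataset_name: str = "",
) -> list[Network]:
    """Greedy construction of up to ``n_networks`` focus-disjoint networks.

    Each network is seeded with the unused focus molecule of highest
    knowledgebase degree to focus molecules, then repeatedly extended by
    the connected candidate with the most edges into the current
    members (ties: focus membership, then total knowledgebase degree,
    then lexicographic id) until ``size`` molecules or no connected
    candidate remains.  Focus molecules used by one network are barred
    from later networks, which keeps ranks meaningful.
    """
    focus_all = {m for m in dataset_molecules if m in kb}
    dropped = set(dataset_molecules) - focus_all
    if dropped:
        warnings.warn(f"{len(dropped)} dataset molecules not in the knowledgebase were dropped")
    if not focus_all:
        warnings.warn("no dataset molecule maps to the knowledgebase; no networks built")
        return []

    used_focus: set[str] = set()
    networks: list[Network] = []
    for _ in range(n_networks):
        avail = focus_all - used_focus
        if not avail:
            break
        seed = min(avail, key=lambda m: (-_edges_into(kb, m, focus_all), m))
        members: set[str] = {seed}
        while len(members) < size:
            candidates = {
                nb
                for m in members
                for nb in kb.neighbors(m)
                if nb not in members and not (nb in used_focus)
            }
            if not candidates:
                break
            # focus molecules first (networks are built around the dataset;
            # knowledgebase molecules act as linkers), then most edges into
            # current members, then higher total kb degree, then
            # lexicographically smallest id
            best = min(
                candidates,
                key=lambda c: (
                    0 if c in focus_all else 1,
                    -_edges_into(kb, c, members),
                    -kb.degree(c),
                    c,
                ),
            )
            members.add(best)
        focus = members & focus_all
        used_focus |= focus
        # keep insertion-independent deterministic order
        ordered = sorted(members)
        networks.append(Network(molecules=ordered, focus=focus, source_dataset=dataset_name))

    n_focus_in_kb = len(focus_all)
    for net in networks:
        net.score = network_score(net, n_focus_in_kb, kb.number_of_nodes())
    networks.sort(key=lambda n: (-n.score, n.molecules))
    for i, net in enumerate(networks):
        net.rank = i + 1
    return networks


def network_score(network: Network, dataset_size_in_kb: int, kb_size: int) -> float:
    """-log10 right-tailed Fisher exact p for focus enrichment.

    P(X >= f) with X ~ Hypergeometric(N = kb_size, K = dataset size in
    the knowledgebase, n = network size).
    """
    if dataset_size_in_kb > kb_size:
        raise ValueError("dataset size cannot exceed knowledgebase size")
    f = len(network.focus)
    n = len(network.molecules)
    if f > min(n, dataset_size_in_kb):
        raise ValueError("focus count exceeds its bounds")
    p = float(stats.hypergeom.sf(f - 1, kb_size, dataset_size_in_kb, n))
    p = min(max(p, 1e-300), 1.0)
    return -math.log10(p)


def grow(
    network: Network,
    candidates: Iterable[str],
    kb: nx.Graph,
    n: int = GROW_N,
) -> Network:
    """Add the top-n candidates with the highest connectivity to the network.

    Candidates are ranked by the number of knowledgebase edges into the
    current members (ties: higher total knowledgebase degree, then
    lexicographic id); candidates with no edge into the network are
    never added.  The returned network keeps the original focus set and
    all knowledgebase edges among its molecules (edges are implied by
    membership: the induced subgraph).
    """
    members = set(network.molecules)
    scored = []
    for c in candidates:
        if c in members or c not in kb:
            continue
        e = _edges_into(kb, c, members)
        if e >= 1:
            scored.append((e, kb.degree(c), c))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    added = [c for _, _, c in scored[:n]]
    return Network(
        molecules=network.molecules + added,
        focus=set(network.focus),
        source_dataset=network.source_dataset,
        score=network.score,
        rank=network.rank,
    )


def merge_and_critical_genes(
    nets_0h: Sequence[Network],
    nets_8h: Sequence[Network],
    de_120h_genes: set[str],
    dataset_molecules: set[str],
    family_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Critical network genes: DE at 120 h and common to both merged networks.

    The top-3 networks of the 0h- and 8h-miRNA datasets are merged by
    union; any member carrying a family id pulls in every same-family
    molecule present in the dataset (gene-family expansion).
    """
    if not nets_0h or not nets_8h:
        raise ValueError("both network lists must be non-empty")
    family_map = family_map or {}
    by_family: dict[str, set[str]] = {}
    for mol in dataset_molecules:
        fam = family_map.get(mol, "")
        if fam:
            by_family.setdefault(fam, set()).add(mol)

    def merged(nets: Sequence[Network]) -> set[str]:
        mols = set().union(*(set(n.molecules) for n in nets[:3]))
        expanded = set(mols)
        for m in mols:
            fam = family_map.get(m, "")
            if fam:
                expanded |= by_family.get(fam, set())
        return expanded

    return de_120h_genes & merged(nets_0h) & merged(nets_8h)


@dataclass
class HubCall:
    """A molecule with top-k within-network degree in >= 2 datasets."""

    molecule: str
    supporting_networks: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_datasets(self) -> int:
        return len({d for d, _r, _deg in self.supporting_networks})


def find_hubs(
    networks_by_dataset: Mapping[str, Sequence[Network]],
    kb: nx.Graph,
    top_k_degree: int = HUB_TOP_K,
) -> list[HubCall]:
    """Hub molecules: high within-network connectivity in >= 2 datasets.

    Per network, molecules are ranked by degree in the induced subgraph
    (ties: lexicographic id) and the top ``top_k_degree`` recorded; a
    molecule is a hub when it makes that list in networks from at least
    two distinct source datasets.
    """
    support: dict[str, list[tuple[str, int, int]]] = {}
    for dataset, nets in networks_by_dataset.items():
        for net in nets:
            deg = net.degrees(kb)
            top = sorted(deg, key=lambda m: (-deg[m], m))[:top_k_degree]
            for m in top:
                support.setdefault(m, []).append((dataset, net.rank, deg[m]))
    hubs = []
    for m, sup in sorted(support.items()):
        if len({d for d, _r, _deg in sup}) >= 2:
            hubs.append(HubCall(molecule=m, supporting_networks=sorted(sup)))
    return hubs


def gene_set_enrichment(
    dataset_genes: set[str], gene_set: set[str], universe: set[str]
) -> tuple[float, float]:
    """Right-tailed Fisher exact test of dataset/gene-set overlap.

    Returns (odds ratio, p).  Both inputs are intersected with the
    universe; an empty universe is an error.
    """
    if not universe:
        raise ValueError("empty universe")
    ds = dataset_genes & universe
    gs = gene_set & universe
    a = len(ds & gs)
    b = len(ds - gs)
    c = len(gs - ds)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def direction_zscore(expected_signs: Mapping[str, int], observed_signs: Mapping[str, int]) -> float | None:
    """Consistency z-score between annotated and observed change directions.

    z = (n_consistent - n_inconsistent) / sqrt(n), over genes carrying
    both an expected and an observed sign.  Returns None when no gene
    qualifies.  This is a simplified directional-consistency score, not
    a full regulator activation z-score.
    """
    n_cons = n_incons = 0
    for g, exp in expected_signs.items():
        obs = observed_signs.get(g)
        if obs is None or exp == 0 or obs == 0:
            continue
        if np.sign(exp) == np.sign(obs):
            n_cons += 1
        else:
            n_incons += 1
    n = n_cons + n_incons
    if n == 0:
        return None
    return (n_cons - n_incons) / math.sqrt(n)
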
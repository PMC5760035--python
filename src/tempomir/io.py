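"""Plain-text readers and writers: TSV tables, GMT gene sets, edge lists, JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .datasets import GroundTruth, InteractionRecord, interactions_from_frame, interactions_to_frame


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    interactions_to_frame(records).to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    return interactions_from_frame(pd.read_csv(path, sep="\t"))


def write_kb(kb: nx.Graph, path: str | Path) -> None:
    """Knowledgebase as an edge-list TSV plus a node-attribute TSV."""
    path = Path(path)
    edges = pd.DataFrame(sorted((min(u, v), max(u, v)) for u, v in kb.edges()), columns=["a", "b"])
    edges.to_csv(path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            {"molecule": m, "type": kb.nodes[m].get("type", "other"), "family_id": kb.nodes[m].get("family_id", "")}
            for m in sorted(kb.nodes)
        ]
    )
    nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)


def read_kb(path: str | Path) -> nx.Graph:
    path = Path(path)
    edges = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    nodes_path = path.with_suffix(".nodes.tsv")
    if nodes_path.exists():
        nodes = pd.read_csv(nodes_path, sep="\t", keep_default_na=False)
        for row in nodes.itertuples(index=False):
            g.add_node(row.molecule, type=row.type, family_id=row.family_id)
    g.add_edges_from(edges.itertuples(index=False, name=None))
    return g


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(set(gene_sets[name])))
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json_dict(json.load(fh))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
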
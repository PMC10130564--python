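"""Mitogenome haplotype collapsing, mutation distances and haplotype network.

Aligned sequences are reduced by complete deletion (every column containing
a gap or ambiguity character in any sequence is removed), identical
sequences are collapsed into haplotypes with per-population counts, and the
haplotypes are connected by a deterministic minimum spanning tree weighted
by Hamming (mutation-count) distances. A non-tree pair is recorded as an
*alternative link* when its distance equals the maximum edge weight on the
tree path between the two haplotypes (an equally parsimonious connection).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

VALID = set("ACGT")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered name -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes: representative sequences (post complete
    deletion), member samples and per-population counts."""

    representatives: dict[str, str]          # haplotype id -> sequence
    members: dict[str, list[str]]            # haplotype id -> sample ids
    counts: pd.DataFrame                     # haplotype x population counts

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)

    def sizes(self) -> dict[str, int]:
        return {h: len(m) for h, m in self.members.items()}


def _complete_deletion(seqs: dict[str, str]) -> dict[str, str]:
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    arr = np.array([list(s.upper()) for s in seqs.values()])
    keep = np.array([set(col) <= VALID for col in arr.T])
    return {name: "".join(row[keep]) for name, row in zip(seqs, arr)}


def collapse_haplotypes(
    aligned_sequences: dict[str, str], population_map: dict[str, str]
) -> HaplotypeTable:
    """Group identical sequences (after complete deletion of gap/ambiguity
    columns) into haplotypes, ordered by first occurrence."""
    clean = _complete_deletion(aligned_sequences)
    reps: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    seq_to_hap: dict[str, str] = {}
    for name, seq in clean.items():
        if seq not in seq_to_hap:
            hap_id = f"H{len(seq_to_hap) + 1}"
            seq_to_hap[seq] = hap_id
            reps[hap_id] = seq
            members[hap_id] = []
        members[seq_to_hap[seq]].append(name)
    pops = sorted(set(population_map.values()))
    counts = pd.DataFrame(0, index=list(reps), columns=pops)
    for hap_id, mm in members.items():
        for name in mm:
            counts.loc[hap_id, population_map[name]] += 1
    return HaplotypeTable(reps, members, counts)


def mutation_distance(h1: str, h2: str) -> int:
    """Hamming count of differing columns between two equal-length
    sequences."""
    if len(h1) != len(h2):
        raise ValueError("sequences must have equal length")
    return sum(a != b for a, b in zip(h1, h2))


def distance_matrix(table: HaplotypeTable) -> pd.DataFrame:
    haps = list(table.representatives)
    mat = np.zeros((len(haps), len(haps)), int)
    for i, a in enumerate(haps):
        for j in range(i + 1, len(haps)):
            d = mutation_distance(table.representatives[a], table.representatives[haps[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=haps, columns=haps)


@dataclass
class HaploNetwork:
    """Haplotype network: node sizes, MST edges and alternative links."""

    sizes: dict[str, int]
    tree_edges: list[tuple[str, str, int]]
    alternative_edges: list[tuple[str, str, int]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, size in self.sizes.items():
            g.add_node(node, size=size)
        for u, v, w in self.tree_edges:
            g.add_edge(u, v, weight=w, kind="tree")
        for u, v, w in self.alternative_edges:
            g.add_edge(u, v, weight=w, kind="alternative")
        return g


def build_network(table: HaplotypeTable, distances: pd.DataFrame | None = None) -> HaploNetwork:
    """Deterministic Kruskal MST over haplotypes plus alternative links.

    Edges are processed in (weight, u, v) lexicographic order so ties break
    reproducibly. A non-tree edge (u, v) is an alternative link iff its
    weight equals the maximum edge weight on the tree path u -> v.
    """
    haps = list(table.representatives)
    if not haps:
        raise ValueError("need at least one haplotype")
    if distances is None:
        distances = distance_matrix(table)
    edges = sorted(
        (int(distances.loc[u, v]), u, v)
        for i, u in enumerate(haps)
        for v in haps[i + 1:]
    )
    parent = {h: h for h in haps}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[str, str, int]] = []
    rest: list[tuple[str, str, int]] = []
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v, w))
        else:
            rest.append((u, v, w))
    g = nx.Graph()
    g.add_weighted_edges_from(tree)
    alt = []
    for u, v, w in rest:
        path = nx.shortest_path(g, u, v)
        path_max = max(g[a][b]["weight"] for a, b in zip(path, path[1:]))
        if w == path_max:
            alt.append((u, v, w))
    return HaploNetwork(sizes=table.sizes(), tree_edges=tree, alternative_edges=alt)


def write_graphml(net: HaploNetwork, path: str | Path) -> Path:
    nx.write_graphml(net.graph(), str(path))
    return Path(path)


def write_dot(net: HaploNetwork, path: str | Path) -> Path:
    """Minimal Graphviz DOT export (dashed style for alternative links)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("graph haplonet {\n")
        for node, size in net.sizes.items():
            fh.write(f'  "{node}" [width={0.3 + 0.1 * size:.2f}];\n')
        for u, v, w in net.tree_edges:
            fh.write(f'  "{u}" -- "{v}" [label={w}];\n')
        for u, v, w in net.alternative_edges:
            fh.write(f'  "{u}" -- "{v}" [label={w}, style=dashed];\n')
        fh.write("}\n")
    return path
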
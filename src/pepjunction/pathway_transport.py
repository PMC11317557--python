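"""Bond-counting tunneling-pathway conductance estimator.

In the pathway picture of nonresonant tunneling, each covalent bond along
the coupling route contributes a multiplicative decay factor eps_C, and a
hydrogen bond decays twice as strongly (eps_C^2), i.e. counts as two
covalent-bond equivalents.  The best route between the two sulfur anchors
is then the path of minimum effective length
``L = n_covalent + w_H * n_hydrogen`` (default w_H = 2), and its relative
coupling decay is ``eps_C ** L``.  Comparing a turn conformer (which can
short-cut through its i -> i+3 H-bond) with an extended conformer
quantifies how secondary structure shortens the tunneling pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .peptide_model import Conformation, backbone_hbond_pairs

__all__ = [
    "DEFAULT_EPS_C",
    "DEFAULT_W_H",
    "PathwayResult",
    "build_pathway_graph",
    "shortest_pathway",
    "compare_conformers",
    "write_edge_list",
]

#: Per-covalent-bond decay factor (standard pathway-model value).
DEFAULT_EPS_C = 0.6
#: Hydrogen-bond weight in covalent-bond equivalents.
DEFAULT_W_H = 2.0
#: O...H distance cutoff for an H-bond edge, A.
DEFAULT_HBOND_CUTOFF = 2.5


@dataclass
class PathwayResult:
    """Minimum effective-length pathway between the sulfur anchors."""

    path: list[int]
    n_covalent: int
    n_hydrogen: int
    effective_length: float
    eps_c: float

    @property
    def relative_decay(self) -> float:
        """eps_C ** L, the pathway coupling relative to zero length."""
        return float(self.eps_c ** self.effective_length)


def build_pathway_graph(conf: Conformation,
                        hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
                        w_h: float = DEFAULT_W_H) -> nx.Graph:
    """Atom graph with covalent edges (weight 1) and hydrogen-bond edges
    (weight ``w_h``) for every backbone i -> i+3 O...H contact below the
    cutoff in this conformation."""
    topo = conf.topology
    g = nx.Graph()
    g.add_nodes_from(a.atom_id for a in topo.atoms)
    for i, j in topo.covalent_bonds:
        g.add_edge(i, j, kind="covalent", weight=1.0)
    for p in backbone_hbond_pairs(topo):
        d = float(np.linalg.norm(conf.coords[p.donor_h_id]
                                 - conf.coords[p.acceptor_o_id]))
        if d < hbond_cutoff:
            g.add_edge(p.acceptor_o_id, p.donor_h_id, kind="hydrogen",
                       weight=float(w_h), distance=d, label=p.label)
    s1, s2 = topo.sulfur_ids()
    if not nx.has_path(g, s1, s2):
        raise ValueError(
            f"sulfur anchors {s1} and {s2} are disconnected in the "
            "pathway graph (missing covalent linkage)")
    return g


def shortest_pathway(graph: nx.Graph, source_s: int, target_s: int,
                     eps_c: float = DEFAULT_EPS_C) -> PathwayResult:
    """Minimum effective-length path between the sulfur anchors.

    Ties in effective length break toward the lexicographically smallest
    node sequence, making the result deterministic.
    """
    if source_s not in graph or target_s not in graph:
        raise ValueError("sulfur node missing from graph")
    try:
        best = min(nx.all_shortest_paths(graph, source_s, target_s,
                                         weight="weight"))
    except nx.NetworkXNoPath:
        raise ValueError(
            f"no path between {source_s} and {target_s}") from None
    n_cov = n_h = 0
    length = 0.0
    for a, b in zip(best, best[1:]):
        e = graph.edges[a, b]
        length += e["weight"]
        if e["kind"] == "hydrogen":
            n_h += 1
        else:
            n_cov += 1
    return PathwayResult(path=list(best), n_covalent=n_cov, n_hydrogen=n_h,
                         effective_length=length, eps_c=eps_c)


def compare_conformers(turn: Conformation, extended: Conformation,
                       eps_c: float = DEFAULT_EPS_C,
                       hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
                       w_h: float = DEFAULT_W_H) -> dict:
    """Pathway comparison between a turn and an extended conformer of the
    same peptide.

    Reports the minimum effective lengths of both conformers, the decay
    ratio ``eps_c ** (L_turn - L_extended)``, and the turn conformer's
    pure through-bond length (hydrogen edges removed) to expose the
    through-bond vs through-H-bond difference.
    """
    if turn.topology.sequence != extended.topology.sequence:
        raise ValueError("conformers must share one topology")
    s1, s2 = turn.topology.sulfur_ids()
    g_turn = build_pathway_graph(turn, hbond_cutoff, w_h)
    g_ext = build_pathway_graph(extended, hbond_cutoff, w_h)
    r_turn = shortest_pathway(g_turn, s1, s2, eps_c)
    r_ext = shortest_pathway(g_ext, s1, s2, eps_c)
    g_cov = g_turn.copy()
    g_cov.remove_edges_from([
        (a, b) for a, b, k in g_cov.edges(data="kind") if k == "hydrogen"])
    r_turn_cov = shortest_pathway(g_cov, s1, s2, eps_c)
    delta = r_turn.effective_length - r_ext.effective_length
    return {
        "turn": r_turn,
        "extended": r_ext,
        "turn_through_bond": r_turn_cov,
        "delta_length": delta,
        "decay_ratio": float(eps_c ** delta),
        "turn_hbond_advantage": r_turn_cov.effective_length
        - r_turn.effective_length,
    }


def write_edge_list(graph: nx.Graph, path) -> None:
    """Export a pathway graph as a TSV edge list."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tkind\tweight\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['kind']}\t{data['weight']}\n")
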
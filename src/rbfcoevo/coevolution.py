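"""Gain/loss reconstruction and triplet co-evolution on a phylogeny.

Binary gene characters (present/absent at the leaves) are mapped onto a
rooted tree with Fitch small parsimony: a bottom-up pass computes candidate
state sets, a top-down pass resolves one most-parsimonious assignment, and
branches where parent and child states differ are reported as gain (0->1)
or loss (1->0) events.  Ties are broken toward the parent's resolved state
(the state change is pushed as early as possible), and an ambiguous root is
resolved toward presence — the focal biogenesis factors are argued to
predate the radiation of the clades analysed, so the root prior leans to
the ancestral gene being there.  All ambiguous nodes are flagged.

The triplet machinery encodes the joint presence/absence of the GTPase gene
*der*, the uL1 ribosomal protein gene *rplA*, and helix H78 of the 23S rRNA
(the three interacting parts of the L1 stalk neighbourhood) as a 3-bit
state, summarizes states per taxonomic class, and extracts the directed
state-transition graph along a phylogeny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix
from .minetwork import mutual_information

#: fixed bit order of the triplet state (most significant bit first)
TRIPLET_BITS = ("der", "rplA", "H78")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path, rooted: bool = True) -> dendropy.Tree:
    """Read a newick tree; leaf labels are genome ids."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    if rooted:
        tree.is_rooted = True
    _assign_node_ids(tree)
    return tree


def _assign_node_ids(tree: dendropy.Tree) -> None:
    """Give every node a stable id: leaf taxon label, or N<k> in preorder."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.node_id = node.taxon.label if node.taxon else f"L{k}"
        else:
            node.node_id = node.label or f"N{k}"
        k += 1


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

@dataclass
class Event:
    parent: str
    child: str
    kind: str  # "gain" | "loss"


@dataclass
class CharacterHistory:
    """One most-parsimonious assignment for a binary character."""

    gene: str
    node_states: dict[str, int]
    events: list[Event]
    score: int
    ambiguous_nodes: set[str] = field(default_factory=set)

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": self.gene, "parent": e.parent, "child": e.child,
              "event": e.kind} for e in self.events],
            columns=["gene", "parent", "child", "event"])


def fitch_reconstruct(tree: dendropy.Tree,
                      leaf_states: Mapping[str, int],
                      gene: str = "trait",
                      root_preference: int = 1) -> CharacterHistory:
    """Fitch small parsimony for one binary character on a rooted tree.

    ``leaf_states`` maps every leaf label to 0/1.  The parsimony score is
    the number of union operations in the bottom-up pass; the resolved
    assignment realizes exactly that many state changes.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    if not hasattr(tree.seed_node, "node_id"):
        _assign_node_ids(tree)

    score = 0
    sets: dict[int, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None or label not in leaf_states:
                raise ValueError(f"leaf {label!r} has no state")
            s = int(leaf_states[label])
            if s not in (0, 1):
                raise ValueError(f"leaf {label!r}: state must be 0/1, got {s}")
            sets[id(node)] = frozenset({s})
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = frozenset.union(*child_sets)
                score += 1

    node_states: dict[str, int] = {}
    ambiguous: set[str] = set()
    events: list[Event] = []
    for node in tree.preorder_node_iter():
        s = sets[id(node)]
        if node.parent_node is None:
            if len(s) > 1:
                state = root_preference
                ambiguous.add(node.node_id)
            else:
                (state,) = s
        else:
            parent_state = node_states[node.parent_node.node_id]
            if parent_state in s:
                state = parent_state
            else:
                (state,) = s  # singleton disjoint from parent
            if len(s) > 1:
                ambiguous.add(node.node_id)
            if state != parent_state:
                kind = "gain" if state == 1 else "loss"
                events.append(Event(node.parent_node.node_id,
                                    node.node_id, kind))
        node_states[node.node_id] = state

    assert len(events) == score, "resolved changes must equal Fitch score"
    return CharacterHistory(gene=gene, node_states=node_states,
                            events=events, score=score,
                            ambiguous_nodes=ambiguous)


def reconstruct_genes(tree: dendropy.Tree, matrix: PresenceAbsenceMatrix,
                      genes: Sequence[str]) -> dict[str, CharacterHistory]:
    """Fitch histories for several genes; genomes absent from the tree are
    dropped (counted in a warning), leaves absent from the matrix error."""
    labels = set(leaf_labels(tree))
    in_matrix = set(matrix.genomes)
    dropped = in_matrix - labels
    if dropped:
        warnings.warn(f"{len(dropped)} genomes not in tree; dropped")
    missing = labels - in_matrix
    if missing:
        raise ValueError(f"tree leaves missing from matrix: {sorted(missing)[:5]}")
    out = {}
    for gene in genes:
        states = {g: int(matrix.values.at[g, gene]) for g in labels}
        out[gene] = fitch_reconstruct(tree, states, gene=gene)
    return out


# ---------------------------------------------------------------------------
# class-resolved conservation
# ---------------------------------------------------------------------------

def per_class_conservation(matrix: PresenceAbsenceMatrix,
                           genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Heatmap-ready conservation ratio per (taxonomic class, gene)."""
    genes = list(genes) if genes is not None else matrix.genes
    rows = []
    for cls, idx in matrix.metadata.groupby("taxon_class").groups.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty
            warnings.warn(f"class {cls!r} empty; skipped")
            continue
        sub = matrix.values.loc[idx, genes]
        for gene in genes:
            rows.append({"taxon_class": cls, "gene": gene,
                         "ratio": float(sub[gene].mean()), "n": len(idx)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# triplet states
# ---------------------------------------------------------------------------

def encode_triplet(der: int, rplA: int, h78: int) -> int:
    """Pack (der, rplA, H78) bits into 0-7, der most significant."""
    return (int(der) << 2) | (int(rplA) << 1) | int(h78)


def decode_triplet(state: int) -> tuple[int, int, int]:
    if not 0 <= state <= 7:
        raise ValueError(f"state out of range: {state}")
    return ((state >> 2) & 1, (state >> 1) & 1, state & 1)


def encode_triplets(matrix: PresenceAbsenceMatrix,
                    h78_calls: Mapping[str, int] | pd.Series,
                    ) -> tuple[pd.DataFrame, int]:
    """Per-genome triplet state from the matrix's der/rplA columns and the
    per-genome H78 presence calls.

    Genomes with no H78 call are excluded; their count is returned.
    """
    calls = pd.Series(h78_calls)
    keep = [g for g in matrix.genomes if g in calls.index]
    n_excluded = len(matrix.genomes) - len(keep)
    der = matrix.values.loc[keep, "der"].astype(int)
    rpla = matrix.values.loc[keep, "rplA"].astype(int)
    h78 = calls.loc[keep].astype(int)
    df = pd.DataFrame({
        "der": der, "rplA": rpla, "H78": h78,
        "state": (der.to_numpy() << 2) | (rpla.to_numpy() << 1)
                 | h78.to_numpy(),
        "taxon_class": matrix.metadata.loc[keep, "taxon_class"],
    }, index=pd.Index(keep, name="genome_id"))
    return df, n_excluded


def class_state_proportions(states: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each triplet state within each class (rows sum to 1)."""
    counts = (states.groupby(["taxon_class", "state"]).size()
              .rename("count").reset_index())
    totals = counts.groupby("taxon_class")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def modal_state_per_class(states: pd.DataFrame) -> pd.Series:
    props = class_state_proportions(states)
    idx = props.groupby("taxon_class")["proportion"].idxmax()
    return props.loc[idx].set_index("taxon_class")["state"]


# ---------------------------------------------------------------------------
# trajectory graphs
# ---------------------------------------------------------------------------

def ancestral_triplet_states(tree: dendropy.Tree,
                             states: pd.DataFrame) -> dict[str, int]:
    """Triplet state at every node, from independent Fitch runs per bit."""
    labels = leaf_labels(tree)
    missing = [l for l in labels if l not in states.index]
    if missing:
        raise ValueError(f"no triplet state for leaves: {missing[:5]}")
    per_bit = {}
    for bit in TRIPLET_BITS:
        hist = fitch_reconstruct(
            tree, {l: int(states.at[l, bit]) for l in labels}, gene=bit)
        per_bit[bit] = hist.node_states
    node_ids = per_bit[TRIPLET_BITS[0]].keys()
    return {
        nid: encode_triplet(per_bit["der"][nid], per_bit["rplA"][nid],
                            per_bit["H78"][nid])
        for nid in node_ids
    }


def _classes_under(node: dendropy.Node,
                   leaf_classes: Mapping[str, str]) -> frozenset[str]:
    return frozenset(leaf_classes[lf.taxon.label]
                     for lf in node.leaf_iter()
                     if lf.taxon.label in leaf_classes)


def trajectory_graph(tree: dendropy.Tree,
                     node_states: Mapping[str, int],
                     leaf_classes: Mapping[str, str]) -> nx.MultiDiGraph:
    """Directed graph of triplet-state transitions along the tree.

    Nodes are observed states (0-7); each branch whose parent and child
    states differ contributes a directed edge annotated with the branch and
    the set of taxonomic classes below the child.
    """
    if not node_states:
        raise ValueError("missing ancestral states")
    g = nx.MultiDiGraph()
    for node in tree.preorder_node_iter():
        g.add_node(node_states[node.node_id])
        if node.parent_node is None:
            continue
        s_parent = node_states[node.parent_node.node_id]
        s_child = node_states[node.node_id]
        if s_parent != s_child:
            g.add_edge(s_parent, s_child,
                       branch=(node.parent_node.node_id, node.node_id),
                       clades=_classes_under(node, leaf_classes))
    return g


def clade_trajectory(tree: dendropy.Tree,
                     node_states: Mapping[str, int],
                     classes: Iterable[str],
                     leaf_classes: Mapping[str, str]) -> list[tuple[int, int]]:
    """State transitions on the path from the root into, and within, the
    subtree spanned by the given taxonomic classes."""
    want = set(classes)
    leaves = [lf for lf in tree.leaf_node_iter()
              if leaf_classes.get(lf.taxon.label) in want]
    if not leaves:
        raise ValueError(f"no leaves in classes {sorted(want)}")
    mrca = tree.mrca(taxa=[lf.taxon for lf in leaves])

    transitions: list[tuple[int, int]] = []
    # root -> mrca path
    path = []
    node = mrca
    while node is not None:
        path.append(node)
        node = node.parent_node
    for parent, child in zip(path[::-1], path[::-1][1:]):
        sp, sc = node_states[parent.node_id], node_states[child.node_id]
        if sp != sc:
            transitions.append((sp, sc))
    # transitions inside the clade
    for node in mrca.preorder_iter():
        if node is mrca or node.parent_node is None:
            continue
        sp = node_states[node.parent_node.node_id]
        sc = node_states[node.node_id]
        if sp != sc:
            transitions.append((sp, sc))
    return transitions


def triplet_mi(states: pd.DataFrame, base: str = "nat") -> dict[str, float]:
    """Pairwise MI between the three triplet bits across genomes."""
    if len(states) < 2:
        raise ValueError("need at least 2 genomes")
    cols = {b: states[b].to_numpy(dtype=int) for b in TRIPLET_BITS}
    return {
        "der~rplA": mutual_information(cols["der"], cols["rplA"], base),
        "rplA~H78": mutual_information(cols["rplA"], cols["H78"], base),
        "der~H78": mutual_information(cols["der"], cols["H78"], base),
    }


def write_history(histories: Mapping[str, CharacterHistory], path) -> None:
    pd.concat([h.events_table() for h in histories.values()],
              ignore_index=True).to_csv(path, sep="\t", index=False)
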
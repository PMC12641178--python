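"""Mutual-information dependency networks over gene presence/absence profiles.

For two genes A and B with empirical presence frequencies the dependency is
the plug-in mutual information

    MI(A,B) = H(A) + H(B) - H(A,B),

with H the Shannon entropy of the marginal / joint presence distributions.
MI is maximal under complete co-variation (co-occurrence or co-absence) and
tends to zero for independent genes.  No pseudocount or continuity
correction is applied: the estimator is the plug-in of the Methods-style
formula, and 0*log(0) counts as 0.

The log base is configurable (natural log by default, base 2 optional) and
every derived object records the base used, since published MI values are
meaningless without it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix

_LN2 = math.log(2.0)

#: tolerance for clipping tiny negative MI caused by floating rounding
NEG_TOL = 1e-12


def _log_scale(base: str) -> float:
    if base in ("nat", "e", "natural"):
        return 1.0
    if base in ("2", 2, "bits"):
        return _LN2
    raise ValueError(f"unknown log base {base!r}; use 'nat' or '2'")


def _entropy_from_probs(p: np.ndarray, scale: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / scale)


def marginal_entropy(column: np.ndarray, base: str = "nat") -> float:
    """Entropy of the empirical Bernoulli distribution of a binary column."""
    col = np.asarray(column)
    if col.size == 0:
        raise ValueError("empty column")
    p1 = float(col.mean())
    return _entropy_from_probs(np.array([p1, 1.0 - p1]), _log_scale(base))


def joint_entropy(col_a: np.ndarray, col_b: np.ndarray,
                  base: str = "nat") -> float:
    """Entropy of the empirical joint distribution over the four cells."""
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty column")
    n = a.size
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = n - n11 - n10 - n01
    p = np.array([n11, n10, n01, n00], dtype=float) / n
    return _entropy_from_probs(p, _log_scale(base))


def mutual_information(col_a: np.ndarray, col_b: np.ndarray,
                       base: str = "nat") -> float:
    """Plug-in MI = H(A) + H(B) - H(A,B), clipped at zero within 1e-12."""
    mi = (marginal_entropy(col_a, base) + marginal_entropy(col_b, base)
          - joint_entropy(col_a, col_b, base))
    if mi < 0:
        if mi < -NEG_TOL:
            raise AssertionError(f"MI underflow beyond tolerance: {mi}")
        mi = 0.0
    return mi


def pairwise_mi(matrix: PresenceAbsenceMatrix,
                genes: list[str] | None = None,
                base: str = "nat") -> pd.DataFrame:
    """MI for every unordered gene pair: exactly n*(n-1)/2 rows.

    Edge rows are canonical (gene_a < gene_b lexicographically).  Constant
    columns (genes absent or present in every genome) give MI 0 with all
    partners and are flagged in the output via the ``constant_a``/
    ``constant_b`` columns.
    """
    sub = matrix if genes is None else matrix.select_genes(genes)
    gene_ids = sub.genes
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes")
    X = sub.values.to_numpy(dtype=np.int64)
    n, g = X.shape
    scale = _log_scale(base)

    ones = X.sum(axis=0)                      # per-gene presence counts
    n11 = X.T @ X                             # co-presence counts
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01

    def plogp(c: np.ndarray) -> np.ndarray:
        p = c / n
        out = np.zeros_like(p, dtype=float)
        nz = p > 0
        out[nz] = p[nz] * np.log(p[nz])
        return out

    h_marg = -(plogp(ones) + plogp(n - ones)) / scale
    h_joint = -(plogp(n11) + plogp(n10) + plogp(n01) + plogp(n00)) / scale
    mi = h_marg[:, None] + h_marg[None, :] - h_joint
    mi = np.where(mi < 0, 0.0, mi)

    const = (ones == 0) | (ones == n)
    iu, ju = np.triu_indices(g, k=1)
    names = np.array(gene_ids, dtype=object)
    ga, gb = names[iu], names[ju]
    ca, cb = const[iu].copy(), const[ju].copy()
    swap = ga > gb
    ga[swap], gb[swap] = gb[swap].copy(), ga[swap].copy()
    ca[swap], cb[swap] = cb[swap].copy(), ca[swap].copy()
    edges = pd.DataFrame({
        "gene_a": ga,
        "gene_b": gb,
        "mi": mi[iu, ju],
        "constant_a": ca,
        "constant_b": cb,
    })
    edges.attrs["base"] = base
    edges.attrs["n_genomes"] = n
    return edges


@dataclass
class DependencyNetwork:
    """Thresholded MI network: retained edges, node roles, the bound used."""

    edges: pd.DataFrame
    threshold: float
    base: str
    isolated: list[str]                       # catalogue genes with no edge

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))


def threshold_network(edges: pd.DataFrame, tau: float = 0.1,
                      all_genes: list[str] | None = None) -> DependencyNetwork:
    """Keep edges with MI >= tau (closed bound).

    ``all_genes`` optionally lists the full catalogue so that genes left
    without any retained edge are reported as isolated nodes rather than
    silently dropped.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    kept = edges[edges["mi"] >= tau].reset_index(drop=True)
    connected = set(kept["gene_a"]) | set(kept["gene_b"])
    isolated = ([g for g in all_genes if g not in connected]
                if all_genes is not None else [])
    return DependencyNetwork(
        edges=kept[["gene_a", "gene_b", "mi"]],
        threshold=tau,
        base=str(edges.attrs.get("base", "nat")),
        isolated=isolated,
    )


def node_stats(network: DependencyNetwork) -> pd.DataFrame:
    """Degree and cumulative edge weight per node, plus the argmax node(s).

    The returned frame is sorted by (weight, degree) descending; ties at the
    top are reported through the ``is_top_degree`` / ``is_top_weight``
    boolean columns (a set, not a single winner).
    """
    if len(network.edges) == 0:
        raise ValueError("empty network")
    e = network.edges
    long = pd.concat([
        e[["gene_a", "mi"]].rename(columns={"gene_a": "gene"}),
        e[["gene_b", "mi"]].rename(columns={"gene_b": "gene"}),
    ])
    stats = long.groupby("gene").agg(degree=("mi", "size"),
                                     weight=("mi", "sum"))
    stats["is_top_degree"] = stats["degree"] == stats["degree"].max()
    stats["is_top_weight"] = np.isclose(stats["weight"],
                                        stats["weight"].max())
    return stats.sort_values(["weight", "degree"], ascending=False)


def hub_gene(network: DependencyNetwork) -> str | None:
    """The hub: unique top node by cumulative weight that also attains the
    maximum degree.  Degree ties are common (partners of a hub inherit each
    other's edges), so weight breaks them; a weight tie yields ``None``."""
    stats = node_stats(network)
    top_w = stats[stats["is_top_weight"]]
    if len(top_w) == 1 and bool(top_w["is_top_degree"].iloc[0]):
        return top_w.index[0]
    return None


def threshold_sweep(edges: pd.DataFrame, taus: list[float],
                    all_genes: list[str] | None = None) -> pd.DataFrame:
    """Edge counts and hub identity across an ascending threshold grid."""
    if sorted(taus) != list(taus):
        raise ValueError("taus must be sorted ascending")
    rows = []
    for tau in taus:
        net = threshold_network(edges, tau, all_genes)
        rows.append({
            "tau": tau,
            "n_edges": len(net.edges),
            "hub": hub_gene(net) if len(net.edges) else None,
        })
    return pd.DataFrame(rows)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_graphml(network: DependencyNetwork, path,
                  roles: dict[str, str] | None = None) -> None:
    """Export the network for external viewers (GraphML via networkx)."""
    import networkx as nx

    g = nx.Graph(threshold=network.threshold, log_base=network.base)
    for node in network.nodes:
        g.add_node(node, role=(roles or {}).get(node, ""))
    for row in network.edges.itertuples():
        g.add_edge(row.gene_a, row.gene_b, mi=float(row.mi))
    for node in network.isolated:
        g.add_node(node, role=(roles or {}).get(node, ""), isolated=True)
    nx.write_graphml(g, path)
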
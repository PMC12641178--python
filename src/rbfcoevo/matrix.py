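"""Binary gene-content matrices and conservation profiling.

The central object is a genomes x genes presence/absence matrix backed by a
pandas DataFrame, with per-genome metadata (group and taxonomic class).
On top of it sit per-genome gene counts, per-group conservation ratios,
their three-way classification (nearly absent / less conserved / highly
conserved), cross-group comparisons and a PCA ordination.

Groups follow the study design: ``CPR`` (Candidate Phyla Radiation,
reduced-genome bacteria), ``nonCPR`` (the bacterial background) and
``symbiotic`` (symbiotic/parasitic bacteria with recently streamlined
genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .catalog import GeneCatalog

GROUPS = ("CPR", "nonCPR", "symbiotic")

NEARLY_ABSENT = "nearly_absent"
LESS_CONSERVED = "less_conserved"
HIGHLY_CONSERVED = "highly_conserved"


@dataclass
class GenomeRecord:
    """One genome: id, group label, taxonomic class, annotation identifiers."""

    genome_id: str
    group: str
    taxon_class: str
    annotations: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if not self.group or not self.taxon_class:
            raise ValueError(
                f"genome {self.genome_id!r}: group and taxon_class required")


class PresenceAbsenceMatrix:
    """Genomes x genes binary matrix with genome metadata.

    ``values`` is a DataFrame of 0/1 with genome ids as index and gene ids
    as columns (column order = catalogue order); ``metadata`` is indexed by
    genome id with columns ``group`` and ``taxon_class``.
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame) -> None:
        if not values.index.equals(metadata.index):
            metadata = metadata.loc[values.index]
        bad = ~values.isin([0, 1]).all(axis=None)
        if bad:
            raise ValueError("matrix cells must be 0/1")
        self.values = values.astype(np.int8)
        self.metadata = metadata

    # -- basic accessors -------------------------------------------------
    @property
    def genomes(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_group(self, group: str) -> "PresenceAbsenceMatrix":
        if group not in set(self.metadata["group"]):
            raise KeyError(f"unknown group label {group!r}")
        keep = self.metadata.index[self.metadata["group"] == group]
        return PresenceAbsenceMatrix(self.values.loc[keep],
                                     self.metadata.loc[keep])

    def select_genes(self, genes: Sequence[str]) -> "PresenceAbsenceMatrix":
        missing = [g for g in genes if g not in self.values.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return PresenceAbsenceMatrix(self.values[list(genes)], self.metadata)

    def column(self, gene: str) -> np.ndarray:
        return self.values[gene].to_numpy()

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path,
               metadata_path: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="genome_id")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t",
                                 index_label="genome_id")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 metadata_path: str | Path) -> "PresenceAbsenceMatrix":
        values = pd.read_csv(path, sep="\t", index_col="genome_id")
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="genome_id",
                               dtype=str)
        return cls(values, metadata)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (genome_id, identifier), one pair per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "identifier"} <= set(df.columns):
        raise ValueError("annotations TSV needs columns genome_id, identifier")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.genome_id, set()).add(row.identifier)
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "group", "taxon_class"} <= set(df.columns):
        raise ValueError(
            "metadata TSV needs columns genome_id, group, taxon_class")
    return df.set_index("genome_id")


def genomes_from_tables(annotations: dict[str, set[str]],
                        metadata: pd.DataFrame) -> list[GenomeRecord]:
    """Join an annotation table and a metadata table into GenomeRecords.

    Every genome in the metadata is kept; genomes without annotation rows
    get an empty annotation set.
    """
    return [
        GenomeRecord(
            genome_id=gid,
            group=str(metadata.at[gid, "group"]),
            taxon_class=str(metadata.at[gid, "taxon_class"]),
            annotations=set(annotations.get(gid, set())),
        )
        for gid in metadata.index
    ]


def build_matrix(genomes: Sequence[GenomeRecord],
                 catalog: GeneCatalog) -> PresenceAbsenceMatrix:
    """Materialize the presence/absence matrix from annotation sets.

    A cell is 1 iff any identifier of the gene (its symbol or any of its KO
    ids) occurs in the genome's annotation set.
    """
    if len(catalog) == 0:
        raise ValueError("catalogue is empty")
    ids = [g.genome_id for g in genomes]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate genome ids: {sorted(dupes)}")
    ident_map = catalog.identifier_map()
    genes = catalog.gene_ids
    col_index = {g: j for j, g in enumerate(genes)}
    arr = np.zeros((len(genomes), len(genes)), dtype=np.int8)
    for i, rec in enumerate(genomes):
        for ident in rec.annotations:
            for gene in ident_map.get(ident, ()):
                arr[i, col_index[gene]] = 1
    values = pd.DataFrame(arr, index=pd.Index(ids, name="genome_id"),
                          columns=genes)
    metadata = pd.DataFrame(
        {"group": [g.group for g in genomes],
         "taxon_class": [g.taxon_class for g in genomes]},
        index=values.index)
    return PresenceAbsenceMatrix(values, metadata)


def gene_count_per_genome(matrix: PresenceAbsenceMatrix,
                          catalog: GeneCatalog,
                          role: str = "RBF") -> pd.Series:
    """Number of catalogue genes of one role present in each genome."""
    genes = [g for g in catalog.genes_by_role(role) if g in matrix.values]
    return matrix.values[genes].sum(axis=1).rename(f"n_{role}")


def rbf_count_per_genome(
    matrix: PresenceAbsenceMatrix, catalog: GeneCatalog,
) -> tuple[pd.Series, pd.Series, dict[str, np.ndarray]]:
    """Per-genome RBF counts, group medians, and per-group histograms.

    Returns ``(counts, group_medians, histograms)`` where ``histograms``
    maps group label to a bincount array over counts 0..n_RBF.
    """
    counts = gene_count_per_genome(matrix, catalog, role="RBF")
    groups = matrix.metadata["group"]
    medians = counts.groupby(groups).median().rename("median_rbf")
    n_rbf = len(catalog.genes_by_role("RBF"))
    hists = {
        grp: np.bincount(counts[groups == grp].to_numpy(), minlength=n_rbf + 1)
        for grp in medians.index
    }
    return counts, medians, hists


def conservation_ratio(matrix: PresenceAbsenceMatrix,
                       group: str) -> pd.DataFrame:
    """Per-gene fraction of genomes in ``group`` carrying the gene.

    Ratios are exact rational counts over the group size.
    """
    sub = matrix.select_group(group)
    n = sub.shape[0]
    present = sub.values.sum(axis=0)
    return pd.DataFrame({
        "gene_id": sub.genes,
        "group": group,
        "ratio": present.to_numpy() / n,
        "n_genomes": n,
    }).set_index("gene_id")


def classify_conservation(profile: pd.DataFrame, low: float = 0.10,
                          high: float = 0.90) -> pd.Series:
    """Three-way conservation category per gene.

    ratio < low -> nearly_absent; low <= ratio <= high -> less_conserved
    (closed interval: exactly 10% or 90% counts as less conserved);
    ratio > high -> highly_conserved.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"invalid thresholds low={low}, high={high}")
    r = profile["ratio"]
    cat = pd.Series(LESS_CONSERVED, index=r.index, name="category",
                    dtype=object)
    cat[r < low] = NEARLY_ABSENT
    cat[r > high] = HIGHLY_CONSERVED
    return cat


def compare_groups(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                   low: float = 0.10, high: float = 0.90) -> pd.DataFrame:
    """Scatter-ready comparison of two conservation profiles.

    Returns one row per gene with both ratios, both categories, and a flag
    ``high_to_less`` marking genes highly conserved in A but only less
    conserved (10%-90% band) in B — the transition the CPR analysis keys on.
    """
    if set(profile_a.index) != set(profile_b.index):
        raise ValueError("profiles cover different gene sets")
    b = profile_b.loc[profile_a.index]
    cat_a = classify_conservation(profile_a, low, high)
    cat_b = classify_conservation(b, low, high)
    out = pd.DataFrame({
        "ratio_a": profile_a["ratio"],
        "ratio_b": b["ratio"],
        "category_a": cat_a,
        "category_b": cat_b,
    })
    out["transition"] = cat_a.str.cat(cat_b, sep="->")
    out["high_to_less"] = (cat_a == HIGHLY_CONSERVED) & (cat_b == LESS_CONSERVED)
    return out


def ordinate(matrix: PresenceAbsenceMatrix,
             n_components: int = 2) -> dict[str, pd.DataFrame | np.ndarray]:
    """PCA of the centered binary matrix.

    Returns per-genome component scores, per-gene loadings, the explained
    variance fractions, and the top-loading genes on each component.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 genomes and 2 genes")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("no variance: matrix columns are constant")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X - X.mean(axis=0))
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=matrix.values.index, columns=pcs)
    loadings = pd.DataFrame(pca.components_.T, index=matrix.values.columns,
                            columns=pcs)
    top = {
        pc: loadings[pc].abs().sort_values(ascending=False).head(4).index.tolist()
        for pc in pcs
    }
    return {
        "scores": scores_df,
        "loadings": loadings,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "top_loading_genes": top,
    }
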
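"""Per-sequence rRNA helix lengths from structure-annotated alignments.

A helix coordinate table (CRW-style, reference-organism nucleotide
numbering, 1-based inclusive) names each helix's 5' and 3' strand segments.
A designated reference row in the alignment bridges those coordinates to
alignment columns; each sequence's helix length is then the number of
non-gap bases it keeps across both segments.  Lineage-specific shortening
is flagged against seed lengths, and helix 78 of the 23S rRNA (part of the
L1 stalk) gets a four-way stem classification: absent, short stem (2-3 bp),
mid stem (6-8 bp), or full length.

Alignment dialect follows covariance-model output: gap symbols are '.',
'-' and '~'; lowercase residues are insert states — they count toward a
sequence's helix length but are excluded from stem-pairing estimates,
because insert columns are not aligned to the consensus structure (and in
these genomes often correspond to intronic insertions spliced from the
mature rRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import AlignIO

GAP_CHARS = frozenset(".-~")
MOLECULES = ("5S", "16S", "23S")

H78_ABSENT = "absent"
H78_SHORT = "short_stem"
H78_MID = "mid_stem"
H78_FULL = "full"


# ---------------------------------------------------------------------------
# helix table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Helix:
    helix_id: str
    molecule: str
    five_prime: tuple[int, int]   # 1-based inclusive reference coordinates
    three_prime: tuple[int, int]

    def __post_init__(self) -> None:
        fs, fe = self.five_prime
        ts, te = self.three_prime
        if not (fs <= fe and ts <= te):
            raise ValueError(f"{self.helix_id}: start must be <= end")
        if fe >= ts:
            raise ValueError(
                f"{self.helix_id}: 5' segment must precede 3' segment")
        if self.molecule not in MOLECULES:
            raise ValueError(f"{self.helix_id}: unknown molecule "
                             f"{self.molecule!r}")


@dataclass(frozen=True)
class HelixTable:
    helices: tuple[Helix, ...]

    def __iter__(self):
        return iter(self.helices)

    def __len__(self) -> int:
        return len(self.helices)

    def get(self, helix_id: str) -> Helix:
        for h in self.helices:
            if h.helix_id == helix_id:
                return h
        raise KeyError(helix_id)

    def for_molecule(self, molecule: str) -> "HelixTable":
        return HelixTable(tuple(h for h in self.helices
                                if h.molecule == molecule))


def load_helix_table(path: str | Path) -> HelixTable:
    df = pd.read_csv(path, sep="\t", dtype={"helix_id": str, "molecule": str})
    need = {"helix_id", "molecule", "fp_start", "fp_end", "tp_start",
            "tp_end"}
    if not need <= set(df.columns):
        raise ValueError(f"helix table needs columns {sorted(need)}")
    return HelixTable(tuple(
        Helix(r.helix_id, r.molecule, (int(r.fp_start), int(r.fp_end)),
              (int(r.tp_start), int(r.tp_end)))
        for r in df.itertuples()))


def write_helix_table(table: HelixTable, path: str | Path) -> None:
    pd.DataFrame([
        {"helix_id": h.helix_id, "molecule": h.molecule,
         "fp_start": h.five_prime[0], "fp_end": h.five_prime[1],
         "tp_start": h.three_prime[0], "tp_end": h.three_prime[1]}
        for h in table
    ]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class StructureAlignment:
    """Gapped alignment with one designated reference row."""

    rows: dict[str, str]
    reference_id: str
    consensus_structure: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_id not in self.rows:
            raise ValueError(
                f"reference row {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_id]


def read_alignment(path: str | Path, reference_id: str,
                   fmt: str | None = None) -> StructureAlignment:
    """Read Stockholm (consensus-structure line honoured) or aligned FASTA."""
    path = Path(path)
    if fmt is None:
        fmt = ("stockholm" if path.suffix in {".sto", ".stk", ".stockholm"}
               else "fasta")
    aln = AlignIO.read(str(path), fmt)
    rows = {rec.id: str(rec.seq) for rec in aln}
    ss = aln.column_annotations.get("secondary_structure") \
        if hasattr(aln, "column_annotations") else None
    return StructureAlignment(rows=rows, reference_id=reference_id,
                              consensus_structure=ss)


def write_stockholm(aln: StructureAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(max(len(i) for i in aln.rows), len("#=GC SS_cons")) + 2
        for name, seq in aln.rows.items():
            fh.write(f"{name:<{width}}{seq}\n")
        if aln.consensus_structure is not None:
            fh.write(f"{'#=GC SS_cons':<{width}}{aln.consensus_structure}\n")
        fh.write("//\n")


def _is_gap(c: str) -> bool:
    return c in GAP_CHARS


# ---------------------------------------------------------------------------
# coordinate mapping and lengths
# ---------------------------------------------------------------------------

def map_reference_coordinates(
    alignment: StructureAlignment, table: HelixTable,
) -> dict[str, tuple[list[int], list[int]]]:
    """Alignment columns (1-based) for each helix's two strand segments.

    Walks the reference row, assigning each ungapped reference position its
    alignment column; helix coordinates beyond the reference's ungapped
    length raise an error naming the helix.
    """
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, c in enumerate(alignment.reference_row, start=1):
        if not _is_gap(c):
            pos += 1
            pos_to_col[pos] = col
    ref_len = pos

    out: dict[str, tuple[list[int], list[int]]] = {}
    for h in table:
        segs = []
        for start, end in (h.five_prime, h.three_prime):
            if end > ref_len:
                raise ValueError(
                    f"helix {h.helix_id}: coordinate {end} beyond reference "
                    f"length {ref_len}")
            segs.append([pos_to_col[p] for p in range(start, end + 1)])
        out[h.helix_id] = (segs[0], segs[1])
    return out


def _segment_counts(row: str, columns: Sequence[int]) -> tuple[int, int]:
    """(all bases, consensus-aligned bases) in a row over given columns."""
    total = aligned = 0
    for col in columns:
        c = row[col - 1]
        if _is_gap(c):
            continue
        total += 1
        if not c.islower():
            aligned += 1
    return total, aligned


def helix_length(row: str,
                 column_ranges: tuple[Sequence[int], Sequence[int]]) -> int:
    """Non-gap base count of one sequence across both helix segments."""
    fp, tp = column_ranges
    return _segment_counts(row, fp)[0] + _segment_counts(row, tp)[0]


def helix_profile(alignment: StructureAlignment,
                  table: HelixTable) -> pd.DataFrame:
    """Length and stem estimate per (sequence, helix).

    ``stem`` is min(5' consensus bases, 3' consensus bases) — a
    deterministic stand-in for the paired stem length of the
    covariance-model consensus.
    """
    ranges = map_reference_coordinates(alignment, table)
    rows = []
    for seq_id, row in alignment.rows.items():
        for h in table:
            fp, tp = ranges[h.helix_id]
            fp_total, fp_aln = _segment_counts(row, fp)
            tp_total, tp_aln = _segment_counts(row, tp)
            rows.append({
                "sequence_id": seq_id, "helix_id": h.helix_id,
                "molecule": h.molecule,
                "length": fp_total + tp_total,
                "stem": min(fp_aln, tp_aln),
            })
    return pd.DataFrame(rows)


def seed_lengths(profiles: pd.DataFrame, seed_ids: Sequence[str]) -> pd.Series:
    """Per-helix seed length: median over the designated seed rows."""
    sub = profiles[profiles["sequence_id"].isin(seed_ids)]
    if sub.empty:
        raise ValueError(f"no profile rows for seed ids {list(seed_ids)}")
    return sub.groupby("helix_id")["length"].median()


def compare_to_seed(profiles: pd.DataFrame,
                    seed: pd.Series | Mapping[str, float],
                    classes: Mapping[str, str],
                    min_reduction: int = 1) -> pd.DataFrame:
    """Flag (class, helix) pairs whose class-median length is shorter than
    the seed length by at least ``min_reduction`` bases."""
    seed = pd.Series(seed)
    df = profiles.copy()
    df["taxon_class"] = df["sequence_id"].map(classes)
    df = df.dropna(subset=["taxon_class"])
    med = (df.groupby(["taxon_class", "helix_id"])["length"].median()
           .rename("class_median").reset_index())
    med["seed_length"] = med["helix_id"].map(seed)
    med["shortened"] = med["class_median"] <= med["seed_length"] - min_reduction
    return med


def classify_h78(stem: int, seed_stem: int,
                 presence_min: int = 2) -> tuple[str, bool]:
    """Four-way H78 stem class; returns (label, ambiguous_flag).

    absent < presence_min; short 2-3 bp; mid 6-8 bp; full >= seed_stem - 1.
    Stem lengths falling between classes get the nearest label, flagged
    ambiguous.
    """
    if stem < presence_min:
        return H78_ABSENT, False
    if 2 <= stem <= 3:
        return H78_SHORT, False
    if 6 <= stem <= 8:
        return H78_MID, False
    if stem >= seed_stem - 1:
        return H78_FULL, False
    if stem in (4, 5):
        return (H78_SHORT, True) if stem == 4 else (H78_MID, True)
    # between the mid band and full length
    return (H78_MID, True) if stem - 8 <= (seed_stem - 1) - stem \
        else (H78_FULL, True)


def h78_classification(profiles: pd.DataFrame, seed_ids: Sequence[str],
                       helix_id: str = "H78",
                       presence_min: int = 2) -> pd.DataFrame:
    """Classify every sequence's H78 and derive binary presence calls."""
    sub = profiles[profiles["helix_id"] == helix_id]
    if sub.empty:
        raise ValueError(f"helix {helix_id!r} not in profiles")
    seed_rows = sub[sub["sequence_id"].isin(seed_ids)]
    if seed_rows.empty:
        raise ValueError(f"no seed rows among {list(seed_ids)}")
    seed_stem = int(seed_rows["stem"].median())
    out = sub[["sequence_id", "length", "stem"]].copy()
    labels, flags = zip(*(classify_h78(int(s), seed_stem, presence_min)
                          for s in out["stem"]))
    out["h78_class"] = labels
    out["ambiguous"] = flags
    out["present"] = (out["h78_class"] != H78_ABSENT).astype(int)
    return out.set_index("sequence_id")


def h78_presence_calls(classification: pd.DataFrame) -> pd.Series:
    """Binary H78 call per genome (absent -> 0, any detectable stem -> 1)."""
    return classification["present"].astype(int)
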
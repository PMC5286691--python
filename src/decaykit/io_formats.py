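"""Tabular containers and strict readers/writers for decay time-course data.

All on-disk formats are plain tab-separated text. Written files carry a
``#`` header comment recording the tool version and the parameters used to
produce them, so any table can be traced back to a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

TIME_COL = "time_min"
COND_COL = "condition"
REP_COL = "replicate"
SPIKEIN_COL = "spikein"

__all__ = [
    "TimeCourseDataset",
    "GeneSetCollection",
    "read_timecourse",
    "write_timecourse",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "sample_name",
]


def sample_name(condition: str, replicate: int | str, time_min: float) -> str:
    """Canonical sample-column name ``<condition>_rep<r>_t<minutes>``."""
    return f"{condition}_rep{replicate}_t{int(time_min)}"


def _stamp(params: dict | None = None) -> str:
    tail = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# decaykit v{__version__}{tail}\n"


@dataclass
class TimeCourseDataset:
    """A transcription shut-off time course: intensities plus sample design.

    Parameters
    ----------
    intensities
        Non-negative fluorescence intensities, genes (rows) x samples
        (columns).  The index holds unique gene/probe identifiers.
    design
        One row per sample (index matches intensity columns) with columns
        ``time_min`` (minutes since transcription shut-off), ``condition``
        (cell-state label, e.g. ``P`` / ``CI7``) and ``replicate``
        (biological replicate id).
    spikein
        Boolean flag per gene row marking external spike-in controls, which
        do not decay and may be used for per-sample normalization.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    spikein: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.spikein is None:
            self.spikein = pd.Series(False, index=self.intensities.index)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        inten, design = self.intensities, self.design
        if inten.index.has_duplicates:
            dups = inten.index[inten.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids: {dups}")
        missing = [c for c in (TIME_COL, COND_COL, REP_COL) if c not in design.columns]
        if missing:
            raise ValueError(f"design is missing required columns: {missing}")
        if set(inten.columns) != set(design.index):
            only_m = sorted(set(inten.columns) - set(design.index))
            only_d = sorted(set(design.index) - set(inten.columns))
            raise ValueError(
                f"matrix/design sample mismatch: only in matrix {only_m[:5]}, "
                f"only in design {only_d[:5]}"
            )
        if (design[TIME_COL] < 0).any():
            bad = design.index[design[TIME_COL] < 0][0]
            raise ValueError(f"negative time for sample {bad!r}")
        triples = design[[TIME_COL, COND_COL, REP_COL]]
        if triples.duplicated().any():
            bad = design.index[triples.duplicated()][0]
            raise ValueError(f"duplicate (time, condition, replicate) triple at sample {bad!r}")
        # Estimability: each (condition, replicate) series needs >= 3 distinct
        # time points including t=0.
        for (cond, rep), grp in design.groupby([COND_COL, REP_COL]):
            times = set(grp[TIME_COL])
            if len(times) < 3 or 0 not in times:
                raise ValueError(
                    f"series ({cond}, rep {rep}) has time points {sorted(times)}; "
                    "need >= 3 distinct time points including 0"
                )
        vals = inten.to_numpy()
        neg = vals < 0
        if neg.any():
            g, s = map(int, list(zip(*neg.nonzero()))[0])
            raise ValueError(
                f"negative intensity for gene {inten.index[g]!r} in sample {inten.columns[s]!r}"
            )
        if not self.spikein.index.equals(inten.index):
            raise ValueError("spikein flags do not align with gene rows")

    # -- conveniences ----------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.intensities.index

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design[COND_COL]:
            if c not in seen:
                seen.append(c)
        return seen

    def gene_subset(self, genes) -> "TimeCourseDataset":
        return TimeCourseDataset(
            self.intensities.loc[genes], self.design.copy(), self.spikein.loc[genes]
        )

    def incomplete_genes(self) -> pd.Index:
        """Genes with at least one missing intensity."""
        return self.genes[self.intensities.isna().any(axis=1)]


@dataclass
class GeneSetCollection:
    """Named gene sets (miRNA target families, GO-style terms) over a universe."""

    universe: list[str]
    sets: dict[str, list[str]] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)
    planted: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, members in self.sets.items():
            outside = [m for m in members if m not in uni]
            if outside:
                raise ValueError(
                    f"set {name!r} has members outside the universe: {outside[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# time-course matrix + design
# ---------------------------------------------------------------------------

def write_timecourse(
    dataset: TimeCourseDataset,
    matrix_path: str | Path,
    design_path: str | Path,
    params: dict | None = None,
) -> None:
    """Write intensities (with spike-in flags) and design as stamped TSVs."""
    mat = dataset.intensities.copy()
    mat.insert(0, SPIKEIN_COL, dataset.spikein.astype(int))
    mat.index.name = "gene"
    with open(matrix_path, "w") as fh:
        fh.write(_stamp(params))
        mat.to_csv(fh, sep="\t")
    design = dataset.design.copy()
    design.index.name = "sample"
    with open(design_path, "w") as fh:
        fh.write(_stamp(params))
        design.to_csv(fh, sep="\t")


def read_timecourse(matrix_path: str | Path, design_path: str | Path) -> TimeCourseDataset:
    """Read and validate a time-course matrix and its sample design.

    The matrix TSV has gene ids in the first column, an optional ``spikein``
    0/1 column, and one column per sample; the design TSV has one row per
    sample with ``time_min``, ``condition`` and ``replicate`` columns.
    Rows with missing intensities are kept and flagged downstream.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#",
                      float_precision="round_trip")
    if SPIKEIN_COL in mat.columns:
        spike = mat.pop(SPIKEIN_COL).astype(bool)
    else:
        spike = pd.Series(False, index=mat.index)
    mat = mat.apply(pd.to_numeric, errors="coerce")
    design = pd.read_csv(design_path, sep="\t", index_col=0, comment="#")
    return TimeCourseDataset(mat, design, spike)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated member ids per line).

    Members absent from ``universe`` are dropped (and counted in a warning);
    sets left empty after harmonization are removed.  Harmonization is
    exact-string and case-sensitive.
    """
    sets: dict[str, list[str]] = {}
    annotations: dict[str, str] = {}
    uni = set(universe) if universe is not None else None
    n_dropped_members = 0
    dropped_sets: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need >= 3 tab-separated "
                    f"fields, got {len(fields)})"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(m for m in members if m))  # dedupe, keep order
            if uni is not None:
                kept = [m for m in members if m in uni]
                n_dropped_members += len(members) - len(kept)
                members = kept
            if not members:
                dropped_sets.append(name)
                continue
            sets[name] = members
            annotations[name] = desc
    if n_dropped_members or dropped_sets:
        warnings.warn(
            f"GMT harmonization dropped {n_dropped_members} out-of-universe members "
            f"and {len(dropped_sets)} empty sets {dropped_sets[:5]}",
            stacklevel=2,
        )
    if universe is None:
        universe = sorted({m for mm in sets.values() for m in mm})
    return GeneSetCollection(list(universe), sets, annotations)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.annotations.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# steady-state expression ratios
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a per-gene log2 expression-ratio table (gene id + >=1 contrast).

    The first contrast column (conventionally ``log2fc_CI7``, the quiescent
    vs proliferating ratio) is mandatory; extra contrasts such as
    ``log2fc_CI14`` are carried along.
    """
    tab = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                      float_precision="round_trip")
    if tab.shape[1] < 1:
        raise ValueError(f"{path}: expression table needs at least one ratio column")
    if tab.index.has_duplicates:
        dups = tab.index[tab.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    return tab.apply(pd.to_numeric, errors="coerce")


def write_expression(table: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    out = table.copy()
    out.index.name = "gene"
    with open(path, "w") as fh:
        fh.write(_stamp(params))
        out.to_csv(fh, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path, params: dict | None = None,
                index: bool = True) -> None:
    """Write any result table as a stamped TSV."""
    with open(path, "w") as fh:
        fh.write(_stamp(params))
        table.to_csv(fh, sep="\t", index=index)
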
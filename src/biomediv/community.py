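"""Species-by-site matrices, species richness, and Faith phylogenetic diversity.

A species is present in a cell if any part of its range overlaps the cell, so
per-cell richness is just a matrix row sum, and per-biome richness counts each
species once in every biome its range touches (biome counts can therefore sum
above the species total). Faith PD for a cell is the total branch length of the
minimal subtree of the reference phylogeny connecting the cell's species,
root-inclusive: the path from the community MRCA up to the tree root is counted,
so a single-species cell has PD equal to that species' root-to-tip distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = [
    "RangeSet",
    "BiomeAssignment",
    "build_community_matrix",
    "richness",
    "faith_pd",
    "read_incidence_tsv",
    "read_biomes_tsv",
]

logger = logging.getLogger(__name__)

#: mapping species_id -> set of cell_id
RangeSet = Mapping[str, "set[str]"]

BIOME_CODES = tuple(f"B{i}" for i in range(1, 15))
#: tropical designation: global runs include the tropical/subtropical
#: grassland-savanna biome B7; Asia runs exclude it (too sparse there).
TROPICAL_GLOBAL = frozenset({"B1", "B2", "B3", "B7"})
TROPICAL_ASIA = frozenset({"B1", "B2", "B3"})


@dataclass(frozen=True)
class BiomeAssignment:
    """Cell -> biome label (B1..B14) plus the set of codes deemed tropical."""

    cell_biome: Mapping[str, str]
    tropical: frozenset[str] = field(default=TROPICAL_GLOBAL)

    def __post_init__(self):
        bad = {b for b in self.cell_biome.values() if b not in BIOME_CODES}
        if bad:
            raise ValueError(f"unknown biome codes: {sorted(bad)}")
        trop = frozenset(self.tropical)
        if not trop or not trop < set(BIOME_CODES):
            raise ValueError("tropical set must be a non-empty strict subset of B1..B14")
        object.__setattr__(self, "tropical", trop)

    def is_tropical(self, cell: str) -> bool:
        return self.cell_biome[cell] in self.tropical


def build_community_matrix(ranges: RangeSet, grid: Iterable[str]) -> pd.DataFrame:
    """0/1 cells-by-species incidence matrix.

    Every grid cell appears as a row (possibly all-zero); entry ``(c, s)`` is 1
    iff ``c`` is in the range of ``s``. A range cell outside the grid is an
    error naming the species and cell.
    """
    grid = sorted(set(grid))
    if not grid:
        raise ValueError("grid is empty")
    cell_pos = {c: i for i, c in enumerate(grid)}
    species = sorted(ranges)
    mat = np.zeros((len(grid), len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        cells = ranges[sp]
        if not cells:
            raise ValueError(f"species {sp} has an empty range")
        for c in cells:
            if c not in cell_pos:
                raise ValueError(f"range cell outside grid: {sp}/{c}")
            mat[cell_pos[c], j] = 1
    return pd.DataFrame(mat, index=pd.Index(grid, name="cell_id"),
                        columns=pd.Index(species, name="species_id"))


def richness(matrix: pd.DataFrame, by: str = "cell",
             biomes: BiomeAssignment | None = None) -> pd.Series:
    """Species richness per cell (row sums) or per biome.

    Per biome, a species counts once in each biome where it occupies at least
    one cell, so a wide-ranging species contributes to several biomes.
    """
    if by == "cell":
        out = matrix.sum(axis=1).astype(int)
        out.index.name = "cell_id"
        out.name = "species_count"
        return out
    if by == "biome":
        if biomes is None:
            raise ValueError("per-biome richness requires a BiomeAssignment")
        labels = pd.Series({c: biomes.cell_biome[c] for c in matrix.index})
        present = matrix.groupby(labels).max()  # species present anywhere in biome
        counts = present.sum(axis=1).astype(int)
        counts = counts.reindex(sorted(set(labels)), fill_value=0)
        counts.index.name = "biome"
        counts.name = "species_count"
        return counts
    raise ValueError(f"by must be 'cell' or 'biome', got {by!r}")


def faith_pd(matrix: pd.DataFrame, tree: Phylogeny) -> pd.Series:
    """Faith phylogenetic diversity (Myr of branch length) per cell.

    Species in the matrix that are not tips of the tree are dropped from PD
    (never from richness) with a logged count, mirroring incomplete supertree
    coverage of described species. PD of an empty cell is 0.
    """
    tip_of = tree.tip_index()
    cols = list(matrix.columns)
    missing = [s for s in cols if s not in tip_of]
    if len(missing) == len(cols):
        raise ValueError("no overlap between community species and tree tips")
    if missing:
        logger.warning("faith_pd: dropping %d species absent from the tree "
                       "(e.g. %s)", len(missing), missing[:5])
    scored = [s for s in cols if s in tip_of]
    sub = matrix[scored].to_numpy(dtype=bool)

    # subtree-presence flags per node, aggregated tips-up; an edge is in the
    # minimal root-inclusive subtree iff any community member is below it
    n_cells = sub.shape[0]
    below = np.zeros((tree.n_nodes, n_cells), dtype=bool)
    for j, sp in enumerate(scored):
        below[tip_of[sp]] = sub[:, j]
    order = tree.postorder()
    for node in order:
        if not tree.is_tip[node] and node != tree.root:
            for c in tree.children[node]:
                below[node] |= below[c]
    pd_vals = tree.length @ below  # root's length is 0, excluded automatically
    return pd.Series(pd_vals, index=matrix.index, name="PD")


# -- TSV I/O ---------------------------------------------------------------

def read_incidence_tsv(path) -> dict[str, set[str]]:
    """Read a (species_id, cell_id) incidence table into a RangeSet."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"species_id", "cell_id"}
    if not need <= set(df.columns):
        raise ValueError(f"incidence table must have columns {sorted(need)}")
    out: dict[str, set[str]] = {}
    for sp, cell in zip(df["species_id"], df["cell_id"]):
        out.setdefault(sp, set()).add(cell)
    return out


def read_biomes_tsv(path, tropical: Iterable[str] = TROPICAL_GLOBAL) -> BiomeAssignment:
    """Read a (cell_id, biome_code) table into a BiomeAssignment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"cell_id", "biome_code"}
    if not need <= set(df.columns):
        raise ValueError(f"biome table must have columns {sorted(need)}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"cell labelled more than once: {dup}")
    return BiomeAssignment(dict(zip(df["cell_id"], df["biome_code"])),
                           frozenset(tropical))
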
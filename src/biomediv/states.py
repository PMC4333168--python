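"""Geographic state coding of species and per-state sampling fractions.

States follow the two-region convention: 1 = endemic to the tropical biomes
(region A), 2 = endemic to the non-tropical biomes (region B), 0 = widespread
in both (AB). Sampling fractions rho_k are the proportion of described species
of each state that appear as tips of the analyzed tree; they enter the
likelihoods as tip initial conditions, controlling for incomplete sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .community import BiomeAssignment, RangeSet

__all__ = ["SamplingFractions", "code_tip_states", "sampling_fractions",
           "clade_sampling_fractions", "read_states_tsv", "write_states_tsv"]

STATE_BOTH, STATE_TROPICAL, STATE_NONTROPICAL = 0, 1, 2


@dataclass(frozen=True)
class SamplingFractions:
    """Per-state sampling fractions (rho0: widespread, rho1: tropical, rho2: non-tropical)."""

    rho0: float
    rho1: float
    rho2: float

    def __post_init__(self):
        for name, v in (("rho0", self.rho0), ("rho1", self.rho1), ("rho2", self.rho2)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def by_state(self) -> dict[int, float]:
        return {0: self.rho0, 1: self.rho1, 2: self.rho2}


def code_tip_states(ranges: RangeSet, biomes: BiomeAssignment) -> dict[str, int]:
    """Code each species into {0, 1, 2} from its range and the biome map.

    State 1 iff every range cell lies in a tropical biome, 2 iff none does,
    0 otherwise. An unlabelled range cell is an error.
    """
    states: dict[str, int] = {}
    for sp, cells in ranges.items():
        trop = nontrop = False
        for c in cells:
            if c not in biomes.cell_biome:
                raise ValueError(f"cell {c} (range of {sp}) has no biome label")
            if biomes.is_tropical(c):
                trop = True
            else:
                nontrop = True
        if trop and nontrop:
            states[sp] = STATE_BOTH
        elif trop:
            states[sp] = STATE_TROPICAL
        else:
            states[sp] = STATE_NONTROPICAL
    return states


def sampling_fractions(states: Mapping[str, int],
                       tree_tips: Iterable[str]) -> SamplingFractions:
    """Per-state sampling fractions from a full described-species state table.

    ``states`` must cover every described species (the denominator); tips not
    in it are an error, as is a state class with no described or no sampled
    species (the likelihood is undefined there).
    """
    tree_tips = set(tree_tips)
    unknown = tree_tips - set(states)
    if unknown:
        raise ValueError(f"tree tips missing from the state table: {sorted(unknown)[:5]}")
    rho = {}
    for k in (0, 1, 2):
        described = [s for s, st in states.items() if st == k]
        if not described:
            raise ValueError(f"no described species with state {k}")
        sampled = sum(1 for s in described if s in tree_tips)
        if sampled == 0:
            raise ValueError(f"no sampled species with state {k}: likelihood undefined")
        rho[k] = sampled / len(described)
    return SamplingFractions(rho0=rho[0], rho1=rho[1], rho2=rho[2])


def clade_sampling_fractions(groups: Mapping[str, str],
                             tree_tips: Iterable[str]) -> pd.Series:
    """Sampling fraction per clade (genus/order) from a species->group table.

    Same ratio as :func:`sampling_fractions` with a grouping column instead of
    a geographic state; used for the per-clade birth-death shift analyses.
    """
    tree_tips = set(tree_tips)
    df = pd.DataFrame({"group": pd.Series(groups),
                       "in_tree": [s in tree_tips for s in groups]})
    frac = df.groupby("group")["in_tree"].mean()
    frac.name = "sampling_fraction"
    return frac


def read_states_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "state": int})
    if not {"species_id", "state"} <= set(df.columns):
        raise ValueError("state table must have columns species_id, state")
    bad = set(df["state"]) - {0, 1, 2}
    if bad:
        raise ValueError(f"states must be in {{0,1,2}}, got {sorted(bad)}")
    if df["species_id"].duplicated().any():
        raise ValueError("duplicate species in state table")
    return dict(zip(df["species_id"], df["state"]))


def write_states_tsv(states: Mapping[str, int], path) -> None:
    pd.DataFrame(sorted(states.items()), columns=["species_id", "state"]) \
        .to_csv(path, sep="\t", index=False)
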
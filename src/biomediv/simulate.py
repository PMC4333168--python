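"""Synthetic-data generators with known ground truth.

Three generators emulate the study's inputs: forward birth-death trees with
piecewise (epoch) rate shifts and binomial subsampling of the extant tips;
trees with tip biome states evolved under the two-region speciation/
extinction/dispersal process; and rectangular grid worlds with a tropical
band of biomes and a latitudinal richness gradient. Every generator is a
pure function of its configuration (the seed is mandatory), and trees are
emitted reconstructed: extinct lineages pruned, only extant sampled tips.

Event simulation uses exponential racing over the live lineages, exact for
piecewise-constant rates (waiting times are re-drawn at epoch boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bdshift import EpochModel
from .community import BIOME_CODES, BiomeAssignment, TROPICAL_GLOBAL
from .geosse import GeoSSEParams
from .phylo import Phylogeny, prune_to_taxa
from .states import SamplingFractions

__all__ = ["SimConfig", "GridWorld", "sim_bd_tree", "sim_geosse_tree",
           "sim_grid_world"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a tree simulation.

    Exactly one stopping rule must be set: ``n_taxa`` (stop when that many
    lineages are alive) or ``span`` (simulate a fixed crown span in Myr).
    ``rho`` subsamples the extant tips binomially — a scalar for birth-death
    runs, per-state ``SamplingFractions`` for geographic runs.
    """

    seed: int
    n_taxa: int | None = None
    span: float | None = None
    epoch_model: EpochModel | None = None
    geosse_params: GeoSSEParams | None = None
    root_state: int = 0
    rho: float | SamplingFractions | None = None
    max_retries: int = 1000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if (self.n_taxa is None) == (self.span is None):
            raise ValueError("set exactly one of n_taxa or span")
        if self.n_taxa is not None and self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.span is not None and self.span <= 0:
            raise ValueError("span must be positive")


class _Forward:
    """Bookkeeping of a forward simulation: nodes, times, lineage states."""

    def __init__(self):
        self.parent: list[int] = []
        self.birth: list[float] = []
        self.end: list[float] = []
        self.state: list[int] = []  # 0=A, 1=B, 2=AB (geosse only)
        self.n_children: list[int] = []

    def add(self, parent: int, t: float, state: int = 0) -> int:
        self.parent.append(parent)
        self.birth.append(t)
        self.end.append(np.nan)
        self.state.append(state)
        self.n_children.append(0)
        if parent >= 0:
            self.n_children[parent] += 1
        return len(self.parent) - 1

    def to_phylogeny(self, extant: dict[int, str]) -> Phylogeny:
        """Full tree (extinct tips included) with labelled terminals."""
        labels: list[str | None] = []
        lengths = []
        for i in range(len(self.parent)):
            lengths.append(0.0 if self.parent[i] < 0
                           else self.end[i] - self.birth[i])
            if self.n_children[i] == 0:
                labels.append(extant.get(i, f"x{i}"))
            else:
                labels.append(None)
        return Phylogeny(self.parent, lengths, labels)


def _reconstructed(fw: _Forward, alive: list[int], t_end: float,
                   keep: list[int]) -> Phylogeny | None:
    """Close off the simulation and prune to the sampled extant tips."""
    for u in alive:
        fw.end[u] = t_end
    if len(keep) < 2:
        return None
    extant = {u: f"t{j + 1}" for j, u in enumerate(keep)}
    full = fw.to_phylogeny(extant)
    return prune_to_taxa(full, set(extant.values()))


def sim_bd_tree(config: SimConfig) -> tuple[Phylogeny, EpochModel]:
    """Forward birth-death tree under a (possibly epoch-shifted) model.

    Starts from two crown lineages at age = span (span stopping) and retries
    until at least two sampled tips survive on *both* root lineages, so the
    crown age of the reconstructed tree equals the configured span — the
    condition the shift likelihood assumes. Taxon-count stopping is supported
    for single-epoch models (shift ages are defined relative to the present,
    which is unknown mid-simulation otherwise).

    Returns the reconstructed tree and an echo of the generating model.
    """
    model = config.epoch_model
    if model is None:
        raise ValueError("sim_bd_tree needs config.epoch_model")
    if config.n_taxa is not None and model.n_shifts > 0:
        raise ValueError("taxon-count stopping requires a single-epoch model")
    rho = 1.0 if config.rho is None else float(config.rho)
    rng = np.random.default_rng(config.seed)

    for _ in range(config.max_retries):
        fw = _Forward()
        root = fw.add(-1, 0.0)
        c1 = fw.add(root, 0.0)
        c2 = fw.add(root, 0.0)
        fw.end[root] = 0.0
        alive = [c1, c2]
        t = 0.0
        span = config.span
        # forward-time epoch boundaries (span stopping only)
        bounds = ([span - a for a in model.shift_ages[::-1]] + [span]
                  if span is not None else [np.inf])
        b_idx = 0
        guard = 0
        while alive:
            guard += 1
            if guard > 2_000_000:
                raise RuntimeError("event budget exceeded in sim_bd_tree")
            if span is not None:
                age = span - t
                lam, mu = (float(v[0]) for v in model.rate_at(age))
            else:
                lam, mu = model.lam[0], model.mu[0]
            n = len(alive)
            total = n * (lam + mu)
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t + wait >= bounds[b_idx]:
                t = bounds[b_idx]
                if span is not None and t >= span:
                    break
                b_idx += 1
                continue
            t += wait
            u = alive.pop(int(rng.integers(n)))
            if rng.random() < lam / (lam + mu):
                alive.append(fw.add(u, t))
                alive.append(fw.add(u, t))
                fw.end[u] = t
                if config.n_taxa is not None and len(alive) >= config.n_taxa:
                    break
            else:
                fw.end[u] = t
        if not alive or len(alive) < 2:
            continue
        keep = [u for u in alive if rho >= 1.0 or rng.random() < rho]
        tree = _reconstructed(fw, alive, t, keep)
        if tree is None:
            continue
        if span is not None:
            # require survivors on both crown lineages: crown age == span
            if abs(tree.height - span) > 1e-9 * span:
                continue
        return tree, model
    raise RuntimeError(f"no surviving tree in {config.max_retries} attempts")


# per-lineage event menus for the geographic simulation; state 0=A, 1=B, 2=AB
def _geosse_menu(p: GeoSSEParams):
    return {
        0: (("spec_AA", p.sA), ("ext", p.xA), ("expand", p.dA)),
        1: (("spec_BB", p.sB), ("ext", p.xB), ("expand", p.dB)),
        2: (("spec_AB_A", p.sA), ("spec_AB_B", p.sB), ("spec_split", p.sAB),
            ("lose_A", p.xA), ("lose_B", p.xB)),
    }


def sim_geosse_tree(config: SimConfig) -> tuple[Phylogeny, dict[str, int]]:
    """Forward two-region simulation: reconstructed tree plus tip states.

    A single root lineage starts in ``config.root_state`` (paper coding:
    1 tropical A, 2 non-tropical B, 0 widespread). Events: an endemic
    speciates within its region, goes extinct, or expands to AB; a widespread
    lineage speciates within either region (daughters AB + endemic), splits
    between regions (daughters A + B), or contracts by regional extinction.
    Tip states are returned in the paper coding, after optional per-state
    subsampling.
    """
    p = config.geosse_params
    if p is None:
        raise ValueError("sim_geosse_tree needs config.geosse_params")
    code_to_internal = {1: 0, 2: 1, 0: 2}
    internal_to_code = {0: 1, 1: 2, 2: 0}
    root_state = code_to_internal[config.root_state]
    menu = _geosse_menu(p)
    state_rate = {s: sum(r for _, r in menu[s]) for s in (0, 1, 2)}
    rho = config.rho
    if rho is None:
        rho_by_code = {0: 1.0, 1: 1.0, 2: 1.0}
    elif isinstance(rho, SamplingFractions):
        rho_by_code = rho.by_state()
    else:
        rho_by_code = {0: float(rho), 1: float(rho), 2: float(rho)}
    rng = np.random.default_rng(config.seed)

    for _ in range(config.max_retries):
        fw = _Forward()
        root = fw.add(-1, 0.0, root_state)
        alive = [root]
        t = 0.0
        guard = 0
        stopped = False
        while alive:
            guard += 1
            if guard > 2_000_000:
                raise RuntimeError("event budget exceeded in sim_geosse_tree")
            rates = np.array([state_rate[fw.state[u]] for u in alive])
            total = float(rates.sum())
            if total <= 0:
                break  # absorbing (all rates zero): stop at current time
            wait = rng.exponential(1.0 / total)
            if config.span is not None and t + wait >= config.span:
                t = config.span
                stopped = True
                break
            t += wait
            i = int(rng.choice(len(alive), p=rates / total))
            u = alive[i]
            events = menu[fw.state[u]]
            probs = np.array([r for _, r in events])
            ev = events[int(rng.choice(len(events), p=probs / probs.sum()))][0]
            if ev == "ext":
                alive.pop(i)
                fw.end[u] = t
            elif ev == "expand":
                fw.state[u] = 2
            elif ev == "lose_A":
                fw.state[u] = 1
            elif ev == "lose_B":
                fw.state[u] = 0
            else:
                daughters = {"spec_AA": (0, 0), "spec_BB": (1, 1),
                             "spec_AB_A": (2, 0), "spec_AB_B": (2, 1),
                             "spec_split": (0, 1)}[ev]
                alive.pop(i)
                fw.end[u] = t
                for st in daughters:
                    alive.append(fw.add(u, t, st))
                if config.n_taxa is not None and len(alive) >= config.n_taxa:
                    stopped = True
                    break
        if not stopped and config.span is None:
            continue
        if len(alive) < 2:
            continue
        keep = []
        for u in alive:
            code = internal_to_code[fw.state[u]]
            if rng.random() < rho_by_code[code]:
                keep.append(u)
        tree = _reconstructed(fw, alive, t, keep)
        if tree is None:
            continue
        extant = {u: f"t{j + 1}" for j, u in enumerate(keep)}
        states = {extant[u]: internal_to_code[fw.state[u]] for u in keep}
        return tree, states
    raise RuntimeError(f"no surviving tree in {config.max_retries} attempts")


@dataclass(frozen=True)
class GridWorld:
    """A synthetic gridded world: ranges, biome labels, grid, coordinates."""

    ranges: dict[str, set]
    biomes: BiomeAssignment
    grid: frozenset
    coords: dict[str, tuple[float, float]]  # cell -> (x, y)
    true_states: dict[str, int] = field(default_factory=dict)


def sim_grid_world(n_rows: int, n_cols: int, tropical_rows: float = 0.3,
                   n_species: int = 200,
                   range_size_dist: Callable[[np.random.Generator], tuple[int, int]] | float = 3.0,
                   gradient_strength: float = 1.0, seed: int = 0) -> GridWorld:
    """Grid world with a tropical band and a latitudinal richness gradient.

    Rows 0..ceil(tropical_rows * n_rows)-1 (the bottom band) carry tropical
    biome codes drawn from {B1, B2, B3, B7}; the rest carry non-tropical
    codes. Species ranges are axis-aligned rectangles whose side lengths come
    from ``range_size_dist`` (a callable, or a mean for a shifted-Poisson
    default) and whose row centers are biased toward the band with weight
    ``exp(-gradient_strength * distance / n_rows)``, so expected richness
    decays away from the tropics; strength 0 gives a uniform world.
    """
    if n_rows <= 0 or n_cols <= 0 or n_species <= 0:
        raise ValueError("dimensions and species count must be positive")
    if not (0.0 < tropical_rows < 1.0):
        raise ValueError("tropical_rows must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_trop = max(1, int(np.ceil(tropical_rows * n_rows)))
    cell_id = lambda r, c: f"r{r:03d}c{c:03d}"  # noqa: E731

    tropical_codes = sorted(TROPICAL_GLOBAL)
    nontrop_codes = [b for b in BIOME_CODES if b not in TROPICAL_GLOBAL]
    cell_biome: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for r in range(n_rows):
        codes = tropical_codes if r < n_trop else nontrop_codes
        for c in range(n_cols):
            cid = cell_id(r, c)
            cell_biome[cid] = codes[int(rng.integers(len(codes)))]
            coords[cid] = (float(c), float(r))
    biomes = BiomeAssignment(cell_biome, TROPICAL_GLOBAL)

    if callable(range_size_dist):
        draw_size = range_size_dist
    else:
        mean = float(range_size_dist)

        def draw_size(g: np.random.Generator) -> tuple[int, int]:
            return (1 + int(g.poisson(mean - 1)), 1 + int(g.poisson(mean - 1)))

    # row-center weights: flat inside the band, exponential decay above it
    dist = np.array([0.0 if r < n_trop else (r - n_trop + 1) for r in range(n_rows)])
    w = np.exp(-gradient_strength * dist / n_rows)
    w /= w.sum()

    ranges: dict[str, set] = {}
    true_states: dict[str, int] = {}
    for j in range(n_species):
        sp = f"S{j + 1:04d}"
        h, wdt = draw_size(rng)
        h, wdt = min(h, n_rows), min(wdt, n_cols)
        r0 = int(rng.choice(n_rows, p=w))
        c0 = int(rng.integers(n_cols))
        # toroidal placement: every cell has the same coverage probability
        # under a uniform center, so gradient 0 really is gradient-free
        rows = [(r0 - h // 2 + i) % n_rows for i in range(h)]
        cols = [(c0 - wdt // 2 + i) % n_cols for i in range(wdt)]
        ranges[sp] = {cell_id(r, c) for r in rows for c in cols}
        in_band = any(r < n_trop for r in rows)
        out_band = any(r >= n_trop for r in rows)
        true_states[sp] = 0 if (in_band and out_band) else (1 if in_band else 2)

    return GridWorld(ranges=ranges, biomes=biomes,
                     grid=frozenset(cell_biome), coords=coords,
                     true_states=true_states)
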
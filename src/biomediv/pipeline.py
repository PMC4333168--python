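"""Run orchestration: configured stage execution with a content-hash manifest.

Two workflows are chained from the stage toggles: diversity mapping
(community matrix -> richness -> Faith PD -> PD~SR residual flags) and
diversification inference (tip states -> sampling fractions -> scenario
battery; tree -> LTT -> shift fitting). Every output file is recorded in a
JSON manifest with its SHA-256 hash, the package version, the seed, and all
effective defaults, so a run is self-describing and reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bdshift import BirthDeathShiftModel, select_shift_count
from .community import (build_community_matrix, faith_pd, read_biomes_tsv,
                        read_incidence_tsv, richness, TROPICAL_GLOBAL)
from .geosse import GeoSSEModel, RATE_NAMES
from .pdsr import PDSRModel
from .phylo import ltt_series, parse_newick
from .states import (code_tip_states, read_states_tsv, sampling_fractions,
                     SamplingFractions)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("richness", "pd", "pdsr", "ltt", "shifts", "geosse")


class PipelineError(RuntimeError):
    """Configuration or pre-flight failure (raised before any stage runs)."""


@dataclass
class RunConfig:
    """Inputs, stage toggles and stage parameters for one pipeline run."""

    outdir: str
    tree: str | None = None
    incidence: str | None = None
    biomes: str | None = None
    states: str | None = None
    coords: str | None = None            # TSV cell_id, x, y (pdsr spatial)
    tropical: list[str] = field(default_factory=lambda: sorted(TROPICAL_GLOBAL))
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    keep_taxa: list[str] | None = None   # optional tip filter (per-order runs)
    degree: int = 2
    spatial: bool = False
    residual_fraction: float = 0.1
    alpha: float = 0.05
    max_shifts: int = 2
    shift_rho: float = 1.0
    rho: list[float] | None = None       # (rho0, rho1, rho2); derived if None
    timedep: bool = False
    mcmc_steps: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise PipelineError(f"unknown stages: {sorted(bad)}")
        need: dict[str, list[str]] = {
            "richness": ["incidence", "biomes"],
            "pd": ["incidence", "biomes", "tree"],
            "pdsr": ["incidence", "biomes", "tree"],
            "ltt": ["tree"],
            "shifts": ["tree"],
            "geosse": ["tree"],
        }
        for stage in self.stages:
            for inp in need[stage]:
                if getattr(self, inp) is None:
                    raise PipelineError(f"stage '{stage}' needs input '{inp}'")
            if stage == "geosse" and self.states is None and (
                    self.incidence is None or self.biomes is None):
                raise PipelineError(
                    "stage 'geosse' needs a states file, or incidence + biomes "
                    "to derive the states")
        for name in ("tree", "incidence", "biomes", "states", "coords"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input file for '{name}' not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Pre-flight validation runs before any work; a stage failure afterwards
    leaves the completed outputs in place and re-raises.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = _sha256(path)

    tree = parse_newick(Path(config.tree).read_text()) if config.tree else None
    if tree is not None and config.keep_taxa:
        from .phylo import prune_to_taxa
        tree = prune_to_taxa(tree, config.keep_taxa)

    ranges = biomes = matrix = None
    if config.incidence and config.biomes:
        ranges = read_incidence_tsv(config.incidence)
        biomes = read_biomes_tsv(config.biomes, tropical=config.tropical)
        grid = set(biomes.cell_biome)
        matrix = build_community_matrix(ranges, grid)

    sr = pd_cell = None
    if "richness" in config.stages:
        sr = richness(matrix, by="cell")
        emit("richness_cell.tsv", sr.reset_index())
        emit("richness_biome.tsv",
             richness(matrix, by="biome", biomes=biomes).reset_index())

    if "pd" in config.stages or "pdsr" in config.stages:
        if sr is None:
            sr = richness(matrix, by="cell")
        pd_cell = faith_pd(matrix, tree)
        tab = pd.DataFrame({"cell_id": sr.index, "SR": sr.to_numpy(),
                            "PD": pd_cell.to_numpy()})
        if config.coords:
            xy = pd.read_csv(config.coords, sep="\t")
            tab = tab.merge(xy, on="cell_id", how="left")
        if "pd" in config.stages:
            emit("diversity_cell.tsv", tab)

    if "pdsr" in config.stages:
        fit = PDSRModel(tab, degree=config.degree, spatial=config.spatial).fit()
        flags = fit.flag_deciles(config.residual_fraction)
        emit("pdsr_residuals.tsv", flags)
        (outdir / "pdsr_summary.txt").write_text(fit.summary() + "\n")
        outputs["pdsr_summary.txt"] = _sha256(outdir / "pdsr_summary.txt")

    if "ltt" in config.stages:
        emit("ltt.tsv", ltt_series(tree))

    if "shifts" in config.stages:
        bd = BirthDeathShiftModel(tree, rho=config.shift_rho)
        fits = bd.fit_sequence(max_shifts=config.max_shifts, seed=config.seed)
        m_sel, pvals = select_shift_count(fits, alpha=config.alpha)
        rows = []
        for f in fits:
            rows.append({
                "m": f.m, "lnL": f.loglik, "k": f.k, "AIC": f.aic,
                "lambda": ";".join(f"{v:.6g}" for v in f.model.lam),
                "mu": ";".join(f"{v:.6g}" for v in f.model.mu),
                "turnover": ";".join(f"{v:.6g}" for v in f.model.turnover()),
                "net_div": ";".join(f"{v:.6g}"
                                    for v in f.model.net_diversification()),
                "shift_ages": ";".join(f"{v:.6g}" for v in f.model.shift_ages),
                "p_vs_prev": "" if f.m == 0 else f"{pvals[f.m - 1]:.6g}",
                "selected": f.m == m_sel,
            })
        emit("shifts.tsv", pd.DataFrame(rows))

    if "geosse" in config.stages:
        if config.states:
            states = read_states_tsv(config.states)
        else:
            states = code_tip_states(ranges, biomes)
        tips = set(tree.tip_labels)
        missing = tips - set(states)
        if missing:
            raise PipelineError(f"tips without states: {sorted(missing)[:5]}")
        if config.rho is not None:
            rho = SamplingFractions(*config.rho)
        else:
            try:
                rho = sampling_fractions(states, tips)
            except ValueError as exc:
                warnings.append(f"sampling fractions not derivable ({exc}); "
                                "assuming complete sampling")
                rho = SamplingFractions(1.0, 1.0, 1.0)
        tip_states = {t: states[t] for t in tips}
        model = GeoSSEModel(tree, tip_states, rho)
        battery = model.fit_battery(timedep=config.timedep, seed=config.seed)
        emit("geosse_scenarios.tsv", battery.table())
        if config.mcmc_steps > 0:
            chain = model.mcmc(battery.best.scenario,
                               n_steps=config.mcmc_steps, seed=config.seed,
                               start=battery.best.params
                               if not config.timedep else None)
            emit("geosse_mcmc.tsv", chain.draws)
        for sid, msg in battery.errors.items():
            warnings.append(f"geosse scenario {sid} failed: {msg}")

    manifest = {
        "package": "biomediv",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": outputs,
        "warnings": warnings,
    }
    # the manifest must list every file present in the output directory
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.name not in outputs:
            outputs[p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest
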
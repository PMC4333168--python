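"""Two-region geographic speciation-extinction-dispersal model (GeoSSE class).

A species is endemic to the tropical region A (state 1), endemic to the
non-tropical region B (state 2), or widespread AB (state 0). Seven rates
govern the process, all per Myr: within-region speciation sA, sB; between-
region speciation sAB (a widespread species splits into one endemic daughter
per region); regional extinction xA, xB (killing an endemic, demoting a
widespread species); and range expansion dA (A -> AB), dB (B -> AB). The
likelihood of a dated tree with tip states is computed by postorder pruning,
integrating extinction probabilities E and partial likelihoods D along each
branch; per-state sampling fractions enter as tip initial conditions.

``GeoSSEModel`` is built from (tree, tip states, sampling fractions); its
``fit`` maximizes the likelihood under one of 16 constraint scenarios, and
``fit_battery`` runs all 16 with AIC model selection. ``mcmc`` draws from the
posterior under independent exponential priors. Rates may change linearly
with age before present (``timedep=True``), ``r(t) = max(0, r0 + m t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._kernels import geosse_prune
from .phylo import Phylogeny, TreeValidationError, validate_dated
from .states import SamplingFractions

__all__ = [
    "GeoSSEParams", "GeoSSELinearParams", "ScenarioSpec", "SCENARIOS",
    "GeoSSEModel", "GeoSSEResults", "ScenarioBattery", "MCMCSample",
    "geosse_loglik", "geosse_loglik_timedep", "fit_scenario",
    "scenario_battery", "mcmc_sample",
]

RATE_NAMES = ("sA", "sB", "sAB", "xA", "xB", "dA", "dB")
#: reporting aliases used in the output tables (T = tropical region A)
RATE_ALIASES = {"sA": "sT", "sB": "sNT", "sAB": "sT-NT",
                "xA": "xT", "xB": "xNT", "dA": "dT", "dB": "dNT"}


@dataclass(frozen=True)
class GeoSSEParams:
    """Time-constant rates (per Myr), all finite and non-negative."""

    sA: float
    sB: float
    sAB: float
    xA: float
    xB: float
    dA: float
    dB: float

    def __post_init__(self):
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    def swap_regions(self) -> "GeoSSEParams":
        """Exchange the roles of regions A and B."""
        return GeoSSEParams(sA=self.sB, sB=self.sA, sAB=self.sAB,
                            xA=self.xB, xB=self.xA, dA=self.dB, dB=self.dA)


@dataclass(frozen=True)
class GeoSSELinearParams:
    """Linear time-dependent rates: rate_j(t) = max(0, r0_j + m_j * t).

    ``t`` is the age before present (0 at the tips), so a positive slope means
    the rate increases into the past. Intercepts must be non-negative; slopes
    are unrestricted (the rate is clamped at 0 where the line goes negative).
    """

    intercepts: GeoSSEParams
    slopes: tuple[float, ...] = (0.0,) * 7  # same order as RATE_NAMES

    def __post_init__(self):
        slopes = tuple(float(v) for v in self.slopes)
        if len(slopes) != 7 or any(not np.isfinite(v) for v in slopes):
            raise ValueError("slopes must be 7 finite values (sA..dB order)")
        object.__setattr__(self, "slopes", slopes)

    def rate_at(self, age: float) -> np.ndarray:
        return np.maximum(0.0, self.intercepts.as_array()
                          + np.asarray(self.slopes) * age)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the 2^4 constraint lattice over the seven rates."""

    id: int
    s_equal: bool = False   # sA = sB
    x_equal: bool = False   # xA = xB
    d_equal: bool = False   # dA = dB
    sab_zero: bool = False  # sAB = 0

    @property
    def k(self) -> int:
        return 7 - sum([self.s_equal, self.x_equal, self.d_equal, self.sab_zero])

    @property
    def free_names(self) -> tuple[str, ...]:
        drop = set()
        if self.s_equal:
            drop.add("sB")
        if self.x_equal:
            drop.add("xB")
        if self.d_equal:
            drop.add("dB")
        if self.sab_zero:
            drop.add("sAB")
        return tuple(n for n in RATE_NAMES if n not in drop)

    def expand(self, free: Sequence[float]) -> GeoSSEParams:
        """Full 7-rate vector from the scenario's free parameters."""
        vals = dict(zip(self.free_names, free))
        if self.s_equal:
            vals["sB"] = vals["sA"]
        if self.x_equal:
            vals["xB"] = vals["xA"]
        if self.d_equal:
            vals["dB"] = vals["dA"]
        if self.sab_zero:
            vals["sAB"] = 0.0
        return GeoSSEParams(**vals)

    def label(self) -> str:
        parts = []
        if self.s_equal:
            parts.append("sA=sB")
        if self.x_equal:
            parts.append("xA=xB")
        if self.d_equal:
            parts.append("dA=dB")
        if self.sab_zero:
            parts.append("sAB=0")
        return ", ".join(parts) if parts else "full"


def _build_scenarios() -> tuple[ScenarioSpec, ...]:
    # Explicit 16-scenario lattice: all combinations of the four constraints,
    # ordered by constraint count with the triple rate-equality scenario
    # (sA=sB, xA=xB, dA=dB) at position 11.
    combos = [
        (),                                             # 1 full
        ("s",), ("x",), ("d",), ("sab",),               # 2-5 singles
        ("s", "x"), ("s", "d"), ("x", "d"),             # 6-8 doubles, sAB free
        ("s", "sab"), ("x", "sab"),                     # 9-10
        ("s", "x", "d"),                                # 11: sA=sB, xA=xB, dA=dB
        ("d", "sab"),                                   # 12
        ("s", "x", "sab"), ("s", "d", "sab"), ("x", "d", "sab"),  # 13-15
        ("s", "x", "d", "sab"),                         # 16 fully constrained
    ]
    return tuple(
        ScenarioSpec(id=i + 1, s_equal="s" in c, x_equal="x" in c,
                     d_equal="d" in c, sab_zero="sab" in c)
        for i, c in enumerate(combos)
    )


SCENARIOS: tuple[ScenarioSpec, ...] = _build_scenarios()

# rate floor far below any resolvable rate: a free rate can approach an
# exact-zero constraint closely enough that nested likelihoods agree to 1e-9
_LOG_LO, _LOG_HI = math.log(1e-12), math.log(20.0)
_SLOPE_BOUND = 1.0  # per Myr^2


class GeoSSEModel:
    """Two-region diversification likelihood on a dated tree with tip states.

    Parameters
    ----------
    tree : Phylogeny
        Ultrametric binary tree (Myr branch lengths).
    tip_states : mapping species_id -> {0, 1, 2}
        1 = tropical endemic (A), 2 = non-tropical endemic (B), 0 = both (AB).
    sampling : SamplingFractions or (rho0, rho1, rho2)
        Per-state sampling fractions.
    root : {"obs", "equal", "survival"}
        Root-state treatment: weight by the relative partial likelihoods
        (default), equal weights, or additionally condition on survival of
        the two root lineages.
    n_steps_height : int
        Integration resolution: the RK4 step targets height / n_steps_height,
        with at least 4 steps per branch.
    """

    def __init__(self, tree: Phylogeny, tip_states: Mapping[str, int],
                 sampling: SamplingFractions | Sequence[float] = (1.0, 1.0, 1.0),
                 root: str = "obs", n_steps_height: int = 1000):
        ult, height = validate_dated(tree)
        if not ult:
            raise TreeValidationError("GeoSSE likelihood requires an ultrametric tree")
        if root not in ("obs", "equal", "survival"):
            raise ValueError("root must be 'obs', 'equal' or 'survival'")
        self.tree = tree
        self.height = height
        self.root_mode = root
        if not isinstance(sampling, SamplingFractions):
            sampling = SamplingFractions(*sampling)
        self.sampling = sampling
        self.h_target = height / n_steps_height

        n = tree.n_nodes
        self._post = tree.postorder().astype(np.int64)
        self._is_tip = tree.is_tip.copy()
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        for v in range(n):
            kids = tree.children[v]
            if kids:
                if len(kids) != 2:
                    raise TreeValidationError(
                        f"node {v} has {len(kids)} children; the likelihood "
                        "requires a binary tree")
                left[v], right[v] = kids
        self._left, self._right = left, right
        ages = tree.ages()
        ages[self._is_tip] = 0.0  # snap tips of a within-tolerance tree
        self._ages = ages

        rho = sampling.by_state()
        d_tips = np.zeros((n, 3))
        self.tip_states = dict(tip_states)
        for label, idx in tree.tip_index().items():
            if label not in self.tip_states:
                raise ValueError(f"tip without a geographic state: {label}")
            st = self.tip_states[label]
            if st == 1:
                d_tips[idx, 0] = rho[1]
            elif st == 2:
                d_tips[idx, 1] = rho[2]
            elif st == 0:
                d_tips[idx, 2] = rho[0]
            else:
                raise ValueError(f"invalid state {st} for tip {label}")
        self._d_tips = d_tips
        self._e_init = np.array([1 - rho[1], 1 - rho[2], 1 - rho[0]])

    # -- likelihood --------------------------------------------------------

    def _loglik_arrays(self, r0: np.ndarray, slopes: np.ndarray) -> float:
        d_root, lognorm, e_root, err = geosse_prune(
            self._post, self._left, self._right, self._is_tip, self._ages,
            self._d_tips, self._e_init, r0, slopes, self.h_target)
        if err >= 0:
            raise FloatingPointError(
                f"partial likelihoods vanished at node {err} (numerical underflow)")
        total = float(d_root.sum())
        if self.root_mode == "equal":
            lik = total / 3.0
        else:
            w = d_root / total
            lik = float((w * d_root).sum())
            if self.root_mode == "survival":
                age = self._ages[self._post[-1]]
                r = np.maximum(0.0, r0 + slopes * age)
                lam_root = np.array([r[0], r[1], r[0] + r[1] + r[2]])
                denom = float((w * lam_root * (1 - e_root) ** 2).sum())
                if denom <= 0:
                    return -np.inf
                lik /= denom
        if lik <= 0:
            return -np.inf
        return math.log(lik) + lognorm

    def loglik(self, params: GeoSSEParams | GeoSSELinearParams) -> float:
        """Log-likelihood at the given (constant or time-linear) rates."""
        if isinstance(params, GeoSSELinearParams):
            return self._loglik_arrays(params.intercepts.as_array(),
                                       np.asarray(params.slopes))
        return self._loglik_arrays(params.as_array(), np.zeros(7))

    # -- ML fitting --------------------------------------------------------

    def _crude_rate(self) -> float:
        n = int(self._is_tip.sum())
        return max(math.log(max(n, 3) / 2) / self.height, 0.01)

    def _start_params(self, scenario: ScenarioSpec) -> dict[str, float]:
        r = self._crude_rate()
        return {"sA": r, "sB": r, "sAB": r / 10, "xA": r / 5, "xB": r / 5,
                "dA": r / 2, "dB": r / 2}

    def fit(self, scenario: ScenarioSpec | int = 1, timedep: bool = False,
            n_restarts: int = 2, seed: int = 0,
            start: GeoSSEParams | None = None) -> "GeoSSEResults":
        """Maximize the likelihood under one constraint scenario.

        Free rates are optimized in log space (slopes, when ``timedep``, on
        the natural scale) with L-BFGS-B from a heuristic start plus seeded
        random restarts; tied parameters are constrained exactly.
        """
        if isinstance(scenario, int):
            scenario = SCENARIOS[scenario - 1]
        rng = np.random.default_rng(seed)
        names = scenario.free_names
        nf = len(names)
        start_vals = self._start_params(scenario)
        if start is not None:
            for n_, v in zip(RATE_NAMES, start.as_array()):
                start_vals[n_] = max(v, 2e-12)
        z0 = np.log(np.clip([start_vals[n_] for n_ in names], 1.2e-12, 19.0))

        if not timedep:
            bounds = [(_LOG_LO, _LOG_HI)] * nf

            def negll(z):
                p = scenario.expand(np.exp(z))
                try:
                    ll = self.loglik(p)
                except FloatingPointError:
                    return 1e12
                return -ll if np.isfinite(ll) else 1e12

            starts = [z0] + [np.clip(z0 + rng.normal(0, 1.0, nf), _LOG_LO, _LOG_HI)
                             for _ in range(n_restarts)]
        else:
            bounds = ([(_LOG_LO, _LOG_HI)] * nf
                      + [(-_SLOPE_BOUND, _SLOPE_BOUND)] * nf)

            def negll(z):
                inter = scenario.expand(np.exp(z[:nf]))
                slopes = self._expand_slopes(scenario, z[nf:])
                try:
                    ll = self._loglik_arrays(inter.as_array(), slopes)
                except FloatingPointError:
                    return 1e12
                return -ll if np.isfinite(ll) else 1e12

            z0 = np.concatenate([z0, np.zeros(nf)])
            starts = [z0]
            for _ in range(n_restarts):
                zr = z0.copy()
                zr[:nf] = np.clip(zr[:nf] + rng.normal(0, 1.0, nf), _LOG_LO, _LOG_HI)
                zr[nf:] = rng.normal(0, 0.01, nf)
                starts.append(zr)

        best = (np.inf, None, False)
        for s in starts:
            res = optimize.minimize(negll, s, method="L-BFGS-B", bounds=bounds)
            if res.fun < best[0]:
                best = (res.fun, res.x, bool(res.success))
        fun, z, ok = best
        if z is None:
            raise RuntimeError("GeoSSE optimization failed from every start")
        if not timedep:
            params: GeoSSEParams | GeoSSELinearParams = scenario.expand(np.exp(z))
            k = scenario.k
        else:
            params = GeoSSELinearParams(
                intercepts=scenario.expand(np.exp(z[:nf])),
                slopes=tuple(self._expand_slopes(scenario, z[nf:])))
            k = 2 * scenario.k
        return GeoSSEResults(model=self, scenario=scenario, params=params,
                             loglik=-fun, k=k, timedep=timedep, converged=ok)

    @staticmethod
    def _expand_slopes(scenario: ScenarioSpec, free_slopes: np.ndarray) -> np.ndarray:
        vals = dict(zip(scenario.free_names, free_slopes))
        if scenario.s_equal:
            vals["sB"] = vals["sA"]
        if scenario.x_equal:
            vals["xB"] = vals["xA"]
        if scenario.d_equal:
            vals["dB"] = vals["dA"]
        if scenario.sab_zero:
            vals["sAB"] = 0.0
        return np.array([vals[n] for n in RATE_NAMES])

    def fit_battery(self, timedep: bool = False, n_restarts: int = 1,
                    seed: int = 0) -> "ScenarioBattery":
        """Fit all 16 scenarios; AIC table, best model, equal-support set.

        The full model is fitted first and its MLE warm-starts the constrained
        fits. A scenario whose optimization raises is recorded as failed, not
        fatal, unless every scenario fails.
        """
        fits: dict[int, GeoSSEResults | None] = {}
        full = self.fit(SCENARIOS[0], timedep=timedep,
                        n_restarts=max(n_restarts, 2), seed=seed)
        fits[1] = full
        warm = full.params.intercepts if timedep else full.params
        errors: dict[int, str] = {}
        for sc in SCENARIOS[1:]:
            try:
                fits[sc.id] = self.fit(sc, timedep=timedep,
                                       n_restarts=n_restarts,
                                       seed=seed + sc.id, start=warm)
            except Exception as exc:  # any single failure is recorded
                fits[sc.id] = None
                errors[sc.id] = str(exc)
        if all(f is None for f in fits.values()):
            raise RuntimeError(f"all scenarios failed: {errors}")
        self._repair_nesting(fits, timedep)
        return ScenarioBattery(fits=fits, errors=errors)

    @staticmethod
    def _constraints(sc: ScenarioSpec) -> frozenset:
        return frozenset(c for c, on in (("s", sc.s_equal), ("x", sc.x_equal),
                                         ("d", sc.d_equal), ("sab", sc.sab_zero))
                         if on)

    def _repair_nesting(self, fits: dict, timedep: bool) -> None:
        """Enforce likelihood nesting across the constraint lattice.

        A more constrained scenario's optimum is feasible for any scenario
        whose constraints are a subset, so the latter can be warm-restarted
        from it whenever optimization left it behind.
        """
        for sc in sorted(SCENARIOS, key=lambda s: -len(self._constraints(s))):
            f = fits.get(sc.id)
            if f is None:
                continue
            mine = self._constraints(sc)
            for other in SCENARIOS:
                g = fits.get(other.id)
                if g is None or other.id == sc.id:
                    continue
                if mine < self._constraints(other) and g.loglik > f.loglik + 1e-9:
                    start = (g.params.intercepts if timedep else g.params)
                    refit = self.fit(sc, timedep=timedep, n_restarts=0,
                                     seed=other.id, start=start)
                    if refit.loglik > f.loglik:
                        f = refit
                        fits[sc.id] = refit

    # -- MCMC --------------------------------------------------------------

    def mcmc(self, scenario: ScenarioSpec | int = 1, n_steps: int = 1000,
             seed: int = 0, timedep: bool = False,
             start: GeoSSEParams | None = None,
             prior_mean: float | None = None) -> "MCMCSample":
        """Metropolis-Hastings posterior sampling of the free rates.

        Priors are independent exponentials with a common mean (default twice
        a crude net-diversification estimate from tip count and tree height).
        Sampling is in log-rate space with per-coordinate normal proposals
        whose step sizes adapt during a discarded warm-up of 20% of the steps.
        The chain is a pure function of the seed.
        """
        if timedep:
            raise NotImplementedError("MCMC is provided for time-constant rates")
        if isinstance(scenario, int):
            scenario = SCENARIOS[scenario - 1]
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        names = scenario.free_names
        nf = len(names)
        mean = 2 * self._crude_rate() if prior_mean is None else prior_mean
        rate_prior = 1.0 / mean
        rng = np.random.default_rng(seed)

        def logpost(z):
            theta = np.exp(z)
            try:
                ll = self.loglik(scenario.expand(theta))
            except FloatingPointError:
                return -np.inf
            if not np.isfinite(ll):
                return -np.inf
            # exponential prior + log-space Jacobian
            return ll + float(np.sum(math.log(rate_prior) - rate_prior * theta + z))

        sv = self._start_params(scenario)
        if start is not None:
            for n_, v in zip(RATE_NAMES, start.as_array()):
                sv[n_] = max(v, 1e-8)
        z = np.log(np.clip([sv[n_] for n_ in names], 1e-8, 19.0))
        lp = logpost(z)
        step = np.full(nf, 0.5)
        n_warm = max(int(0.2 * n_steps), 1)
        window, win_acc, win_n = 50, np.zeros(nf), 0
        draws = np.empty((n_steps, nf))
        accepted = 0
        for it in range(n_warm + n_steps):
            warm = it < n_warm
            for j in range(nf):  # coordinate-wise MH sweep
                zprop = z.copy()
                zprop[j] += step[j] * rng.normal()
                lpp = logpost(zprop)
                if math.log(rng.random()) < lpp - lp:
                    z, lp = zprop, lpp
                    if warm:
                        win_acc[j] += 1
                    else:
                        accepted += 1
            if warm:
                win_n += 1
                if win_n == window or it == n_warm - 1:
                    if win_acc.sum() == 0 and win_n >= window:
                        raise RuntimeError(
                            "zero MCMC acceptance over a full adaptation window; "
                            "reduce the proposal step size")
                    rate = win_acc / win_n
                    step *= np.exp(rate - 0.3)
                    step = np.clip(step, 1e-3, 5.0)
                    win_acc[:], win_n = 0, 0
            else:
                draws[it - n_warm] = np.exp(z)
        df = pd.DataFrame(draws, columns=list(names))
        return MCMCSample(scenario=scenario, draws=df,
                          acceptance_rate=accepted / (n_steps * nf),
                          n_warmup=n_warm, seed=seed, prior_mean=mean)


@dataclass
class GeoSSEResults:
    """Maximum-likelihood fit of one scenario: rates, lnL, AIC."""

    model: GeoSSEModel
    scenario: ScenarioSpec
    params: GeoSSEParams | GeoSSELinearParams
    loglik: float
    k: int
    timedep: bool = False
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def rates(self) -> dict[str, float]:
        p = self.params.intercepts if self.timedep else self.params
        return {n: getattr(p, n) for n in RATE_NAMES}

    def summary(self) -> str:
        lines = [f"GeoSSE scenario {self.scenario.id} ({self.scenario.label()})"
                 f"{' + linear time dependence' if self.timedep else ''}",
                 f"  lnL = {self.loglik:.4f}   k = {self.k}   AIC = {self.aic:.2f}"]
        for n, v in self.rates().items():
            lines.append(f"  {RATE_ALIASES[n]:>6s} ({n}): {v:.6g}")
        if self.timedep:
            for n, s in zip(RATE_NAMES, self.params.slopes):
                lines.append(f"  {n}.m: {s:.6g}")
        return "\n".join(lines)


@dataclass
class ScenarioBattery:
    """All-scenario fit table with AIC-based model selection."""

    fits: dict[int, GeoSSEResults | None]
    errors: dict[int, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.fits):
            f = self.fits[sid]
            sc = SCENARIOS[sid - 1]
            row = {"scenario": sid, "constraints": sc.label(), "k": sc.k,
                   "lnL": np.nan, "AIC": np.nan}
            row.update({n: np.nan for n in RATE_NAMES})
            if f is not None:
                row.update({"k": f.k, "lnL": f.loglik, "AIC": f.aic})
                row.update(f.rates())
            rows.append(row)
        df = pd.DataFrame(rows)
        df["dAIC"] = df["AIC"] - df["AIC"].min()
        return df

    @property
    def best(self) -> GeoSSEResults:
        ok = [f for f in self.fits.values() if f is not None]
        return min(ok, key=lambda f: f.aic)

    def supported(self, delta: float = 2.0) -> list[GeoSSEResults]:
        """Models within ``delta`` AIC of the best (equal-support set)."""
        best_aic = self.best.aic
        return [f for f in self.fits.values()
                if f is not None and f.aic - best_aic < delta]

    def summary(self) -> str:
        df = self.table().sort_values("dAIC")
        cols = ["scenario", "constraints", "k", "lnL", "AIC", "dAIC"]
        sup = [f.scenario.id for f in self.supported()]
        return (df[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}")
                + f"\nequally supported (dAIC < 2): scenarios {sorted(sup)}")


@dataclass
class MCMCSample:
    """Posterior draws for one scenario's free rates."""

    scenario: ScenarioSpec
    draws: pd.DataFrame
    acceptance_rate: float
    n_warmup: int
    seed: int
    prior_mean: float

    def summary(self) -> pd.DataFrame:
        q = self.draws.quantile([0.025, 0.5, 0.975]).T
        q.columns = ["q2.5", "median", "q97.5"]
        q.insert(0, "mean", self.draws.mean())
        return q


# -- functional surface ----------------------------------------------------

def geosse_loglik(tree: Phylogeny, states: Mapping[str, int],
                  params: GeoSSEParams,
                  sampling: SamplingFractions | Sequence[float] = (1, 1, 1),
                  root: str = "obs") -> float:
    return GeoSSEModel(tree, states, sampling, root=root).loglik(params)


def geosse_loglik_timedep(tree: Phylogeny, states: Mapping[str, int],
                          params: GeoSSELinearParams,
                          sampling: SamplingFractions | Sequence[float] = (1, 1, 1),
                          root: str = "obs") -> float:
    return GeoSSEModel(tree, states, sampling, root=root).loglik(params)


def fit_scenario(tree, states, sampling, scenario=1, timedep=False, **kw):
    return GeoSSEModel(tree, states, sampling).fit(scenario, timedep=timedep, **kw)


def scenario_battery(tree, states, sampling, timedep=False, **kw):
    return GeoSSEModel(tree, states, sampling).fit_battery(timedep=timedep, **kw)


def mcmc_sample(tree, states, sampling, scenario=1, n_steps=1000, seed=0, **kw):
    return GeoSSEModel(tree, states, sampling).mcmc(scenario, n_steps=n_steps,
                                                    seed=seed, **kw)
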
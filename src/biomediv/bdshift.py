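"""Piecewise-constant birth-death likelihood and diversification-shift fitting.

The model: a reconstructed (extant, incompletely sampled) ultrametric tree is
generated by a birth-death process whose speciation rate lambda and extinction
rate mu are constant within epochs separated by m shift ages, with present-day
sampling fraction rho. Within an epoch the survival probability
``F(t) = 1 - p0(t)`` (a lineage alive at age t leaves at least one sampled
descendant) obeys the logistic ODE ``F' = (lambda - mu) F - lambda F^2`` and
the reconstructed-lineage density ``q(t) = p1(t)`` obeys
``q' = (lambda - mu - 2 lambda (1 - F)) q``; both admit closed forms that are
propagated across shift ages by continuity, so no numerical integration is
needed. With branching times ``x_1 >= ... >= x_{n-1}`` (root first), the
log-likelihood conditioned on survival of both root lineages is

    lnL = 2 [ln q(x_1) - ln F(x_1)] + sum_{i>=2} [ln lambda(x_i) + ln q(x_i)]

Maximum-likelihood fitting searches shift ages on a grid (exhaustive for
m <= 2, greedy placement with coordinate refinement above) and optimizes
per-epoch rates in log space; model count m is selected by forward likelihood
ratio tests with 3 degrees of freedom per added shift (two rates + one age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .phylo import Phylogeny

__all__ = ["EpochModel", "ShiftFit", "BirthDeathShiftModel", "bd_loglik",
           "select_shift_count"]

_RATE_LO, _RATE_HI = 1e-6, 10.0  # per-Myr bounds for optimized rates


@dataclass(frozen=True)
class EpochModel:
    """Piecewise-constant birth-death rates with sampling at present.

    ``shift_ages`` are strictly decreasing ages before present (Mya); epoch i
    (0-based, oldest first) spans ``(shift_ages[i], shift_ages[i-1])`` with the
    root side unbounded, and the last epoch ends at the present. ``lam`` and
    ``mu`` are per-epoch speciation/extinction rates (per Myr), oldest epoch
    first, of length ``len(shift_ages) + 1``.
    """

    lam: tuple[float, ...]
    mu: tuple[float, ...]
    shift_ages: tuple[float, ...] = ()
    rho: float = 1.0

    def __post_init__(self):
        lam = tuple(float(v) for v in np.atleast_1d(self.lam))
        mu = tuple(float(v) for v in np.atleast_1d(self.mu))
        ages = tuple(float(v) for v in np.atleast_1d(np.asarray(self.shift_ages, dtype=float)))
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "shift_ages", ages)
        if len(lam) != len(mu) or len(lam) != len(ages) + 1:
            raise ValueError("need len(lam) == len(mu) == len(shift_ages) + 1")
        if any(not np.isfinite(v) or v < 0 for v in lam + mu):
            raise ValueError("rates must be finite and non-negative")
        if any(a <= 0 for a in ages):
            raise ValueError("shift ages must be positive (ages before present)")
        if any(ages[i] <= ages[i + 1] for i in range(len(ages) - 1)):
            raise ValueError("shift ages must be strictly decreasing")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")

    @property
    def n_shifts(self) -> int:
        return len(self.shift_ages)

    def epoch_of(self, age) -> np.ndarray:
        """Epoch index (oldest-first) containing each age."""
        bounds = np.asarray(self.shift_ages)  # descending
        return np.searchsorted(-bounds, -np.atleast_1d(age), side="right")

    def rate_at(self, age):
        idx = self.epoch_of(age)
        return np.asarray(self.lam)[idx], np.asarray(self.mu)[idx]

    def turnover(self) -> np.ndarray:
        """Per-epoch extinction/speciation ratio (oldest epoch first)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.asarray(self.mu) / np.asarray(self.lam)

    def net_diversification(self) -> np.ndarray:
        return np.asarray(self.lam) - np.asarray(self.mu)


def _propagate(model: EpochModel):
    """ln F and ln q at each epoch's present-side boundary, youngest first.

    Returns (boundary ages ascending incl. 0, lnF at boundaries, lnq at
    boundaries, per-boundary-epoch lam, mu) for vectorized within-epoch
    evaluation.
    """
    ages = np.concatenate(([0.0], np.asarray(model.shift_ages)[::-1]))
    lam = np.asarray(model.lam)[::-1]  # youngest epoch first
    mu = np.asarray(model.mu)[::-1]
    lnF = np.empty_like(ages)
    lnq = np.empty_like(ages)
    lnF[0] = math.log(model.rho)
    lnq[0] = math.log(model.rho)
    for j in range(len(ages) - 1):
        dt = ages[j + 1] - ages[j]
        lnFj, lnqj = _step(lnF[j], lnq[j], lam[j], mu[j], dt)
        lnF[j + 1], lnq[j + 1] = lnFj, lnqj
    return ages, lnF, lnq, lam, mu


def _step(lnF0: float, lnq0: float, lam: float, mu: float, dt):
    """Closed-form propagation of (ln F, ln q) over dt within one epoch."""
    c = lam - mu
    cdt = c * dt
    # (e^{c dt} - 1)/c, stable as c -> 0
    if np.isscalar(cdt):
        g = dt * (1 + cdt / 2) if abs(cdt) < 1e-8 else np.expm1(cdt) / c
    else:
        g = np.where(np.abs(cdt) < 1e-8, dt * (1 + cdt / 2),
                     np.expm1(np.where(np.abs(cdt) < 1e-8, 0.0, cdt))
                     / np.where(c == 0, 1.0, c))
    lnD = np.log1p(lam * np.exp(lnF0) * g)  # denominator >= 1: stable
    return lnF0 + cdt - lnD, lnq0 + cdt - 2 * lnD


def bd_loglik(tree: Phylogeny, model: EpochModel,
              condition_on_survival: bool = True) -> float:
    """Log-likelihood of the tree's branching times under the epoch model.

    Invariant to tip relabelling (depends on branching times only) and
    continuous in the shift ages. Conditioning on survival of both root
    lineages to the present is the default and can be switched off.
    """
    x = tree.branching_times()  # descending; validates ultrametricity
    height = x[0]
    for a in model.shift_ages:
        if not (0.0 < a < height):
            raise ValueError(f"shift age {a} outside (0, tree height {height:.6g})")
    return _bd_loglik_times(x, model, condition_on_survival)


def _bd_loglik_times(x: np.ndarray, model: EpochModel,
                     condition_on_survival: bool = True) -> float:
    ages, lnF_b, lnq_b, lam_y, mu_y = _propagate(model)
    # epoch (youngest-first) of each branching time
    idx = np.searchsorted(ages, x, side="right") - 1
    dt = x - ages[idx]
    lnF_x, lnq_x = _step(lnF_b[idx], lnq_b[idx], lam_y[idx], mu_y[idx], dt)
    with np.errstate(divide="ignore"):
        ln_lam = np.log(lam_y[idx])
    ll = 2.0 * lnq_x[0] + float(np.sum(ln_lam[1:] + lnq_x[1:]))
    if condition_on_survival:
        ll -= 2.0 * lnF_x[0]
    return ll


@dataclass
class ShiftFit:
    """Maximum-likelihood fit for a fixed number of shifts m."""

    model: EpochModel
    loglik: float
    m: int
    converged: bool = True
    pvalue_vs_prev: float | None = None

    @property
    def k(self) -> int:
        """Free parameters: 2 rates per epoch plus one age per shift."""
        return 2 * (self.m + 1) + self.m

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def summary(self) -> str:
        em = self.model
        lines = [f"birth-death shift fit: m = {self.m} shifts, "
                 f"lnL = {self.loglik:.4f}, k = {self.k}, AIC = {self.aic:.2f}",
                 f"  rho = {em.rho:g}",
                 "  epoch (oldest first): lambda  mu  turnover  net_div"]
        to, nd = em.turnover(), em.net_diversification()
        for i in range(self.m + 1):
            lines.append(f"    {i}: {em.lam[i]:.4f}  {em.mu[i]:.4f}  "
                         f"{to[i]:.3f}  {nd[i]:.4f}")
        if em.shift_ages:
            lines.append("  shift ages (Mya): "
                         + ", ".join(f"{a:.2f}" for a in em.shift_ages))
        return "\n".join(lines)


class BirthDeathShiftModel:
    """ML estimation of piecewise birth-death rates and shift ages on a tree.

    Parameters
    ----------
    tree : Phylogeny
        Dated ultrametric tree.
    rho : float
        Present-day sampling fraction in (0, 1].
    condition_on_survival : bool
        Condition the likelihood on both root lineages surviving (default).
    """

    def __init__(self, tree: Phylogeny, rho: float = 1.0,
                 condition_on_survival: bool = True):
        if not (0.0 < rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        self.tree = tree
        self.rho = rho
        self.condition_on_survival = condition_on_survival
        self.x = tree.branching_times()
        self.height = float(self.x[0])

    def loglik(self, model: EpochModel) -> float:
        return bd_loglik(self.tree, model, self.condition_on_survival)

    # -- rate optimization at fixed shift ages -----------------------------

    def _negll(self, log_rates: np.ndarray, ages: tuple[float, ...]) -> float:
        r = np.exp(log_rates)
        n_ep = len(ages) + 1
        model = EpochModel(lam=tuple(r[:n_ep]), mu=tuple(r[n_ep:]),
                           shift_ages=ages, rho=self.rho)
        ll = _bd_loglik_times(self.x, model, self.condition_on_survival)
        return -ll if np.isfinite(ll) else 1e12

    def _fit_rates(self, ages: tuple[float, ...],
                   starts: list[np.ndarray]) -> tuple[float, np.ndarray]:
        n_par = 2 * (len(ages) + 1)
        bounds = [(math.log(_RATE_LO), math.log(_RATE_HI))] * n_par
        best = (np.inf, None)
        for x0 in starts:
            res = optimize.minimize(self._negll, x0, args=(ages,),
                                    method="L-BFGS-B", bounds=bounds)
            if res.fun < best[0]:
                best = (res.fun, res.x)
        return best

    def _default_starts(self, n_epochs: int, rng: np.random.Generator,
                        n_restarts: int) -> list[np.ndarray]:
        n_tips = len(self.x) + 1
        crude = max(math.log(n_tips / 2) / self.height, 0.01)  # crown Yule rate
        base = np.concatenate([np.full(n_epochs, math.log(crude)),
                               np.full(n_epochs, math.log(max(crude / 5, _RATE_LO * 10)))])
        starts = [base]
        lo, hi = math.log(_RATE_LO), math.log(_RATE_HI)
        for _ in range(n_restarts):
            starts.append(np.clip(base + rng.normal(0, 1.5, size=base.size), lo, hi))
        return starts

    # -- shift-age search --------------------------------------------------

    def _age_grid(self, grid_step: float | None) -> np.ndarray:
        step = self.height / 100.0 if grid_step is None else float(grid_step)
        if step <= 0:
            raise ValueError("grid_step must be positive")
        # bounded one step away from the present and the root
        return np.arange(step, self.height - step / 2, step)

    def fit(self, m: int = 0, grid_step: float | None = None,
            n_restarts: int = 5, seed: int = 0,
            prev: "ShiftFit | None" = None) -> ShiftFit:
        """ML fit with exactly m shifts.

        Shift ages are searched exhaustively on the age grid for m <= 2 and by
        greedy placement plus coordinate refinement above; per-epoch rates are
        optimized in log space with seeded random restarts. Passing the m-1
        fit as ``prev`` warm-starts the search and guarantees the nested
        likelihood is never below the simpler model's.
        """
        n_internal = len(self.x)
        if m > n_internal - 1:
            raise ValueError(f"m = {m} exceeds internal nodes - 1 = {n_internal - 1}")
        rng = np.random.default_rng(seed)
        if m == 0:
            f, xbest = self._fit_rates((), self._default_starts(1, rng, n_restarts))
            r = np.exp(xbest)
            model = EpochModel(lam=(r[0],), mu=(r[1],), rho=self.rho)
            return ShiftFit(model=model, loglik=-f, m=0)

        grid = self._age_grid(grid_step)
        warm = self._embed_start(prev, m) if prev is not None else None
        base_starts = self._default_starts(m + 1, rng, 1)

        def rates_at(ages: tuple[float, ...], carry: np.ndarray | None):
            # grid scan: one warm start per point (carried along the scan);
            # the winning ages get a full multi-restart polish afterwards
            if carry is not None:
                starts = [carry]
            else:
                starts = list(base_starts)
                if warm is not None:
                    starts.append(warm[1])
            return self._fit_rates(ages, starts)

        if m <= 2:
            from itertools import combinations
            best = (np.inf, None, None)
            carry = None
            for combo in combinations(grid[::-1], m):  # descending age tuples
                ages = tuple(sorted(combo, reverse=True))
                f, xb = rates_at(ages, carry)
                carry = xb
                if f < best[0]:
                    best = (f, ages, xb)
            f, ages, xb = best
        else:
            if prev is None:
                prev = self.fit(m - 1, grid_step=grid_step,
                                n_restarts=n_restarts, seed=seed)
            base_ages = list(prev.model.shift_ages)
            best = (np.inf, None, None)
            carry = None
            for a in grid:  # greedy: place the new shift
                if any(abs(a - b) < 1e-9 for b in base_ages):
                    continue
                ages = tuple(sorted(base_ages + [a], reverse=True))
                f, xb = rates_at(ages, carry)
                carry = xb
                if f < best[0]:
                    best = (f, ages, xb)
            # coordinate refinement: rescan each age on the grid
            improved = True
            passes = 0
            while improved and passes < 2:
                improved, passes = False, passes + 1
                f0, ages0, xb0 = best
                for pos in range(m):
                    others = [a for i, a in enumerate(ages0) if i != pos]
                    for a in grid:
                        if any(abs(a - b) < 1e-9 for b in others):
                            continue
                        ages = tuple(sorted(others + [a], reverse=True))
                        f, xb = rates_at(ages, best[2])
                        if f < best[0] - 1e-10:
                            best = (f, ages, xb)
                            improved = True
                    ages0 = best[1]
            f, ages, xb = best

        # final polish with full restarts at the best ages
        f2, xb2 = self._fit_rates(ages, [xb] + self._default_starts(m + 1, rng, n_restarts))
        if f2 < f:
            f, xb = f2, xb2
        r = np.exp(xb)
        model = EpochModel(lam=tuple(r[:m + 1]), mu=tuple(r[m + 1:]),
                           shift_ages=ages, rho=self.rho)
        fit = ShiftFit(model=model, loglik=-f, m=m)
        if prev is not None and fit.loglik < prev.loglik:
            # degenerate embedding of the simpler model can never be beaten
            # downward; keep the embedded model if optimization stalled
            ages_e, x_e = self._embed_start(prev, m)
            r = np.exp(x_e)
            model = EpochModel(lam=tuple(r[:m + 1]), mu=tuple(r[m + 1:]),
                               shift_ages=ages_e, rho=self.rho)
            fit = ShiftFit(model=model, loglik=prev.loglik, m=m, converged=False)
        return fit

    def _embed_start(self, prev: ShiftFit, m: int):
        """Duplicate the previous fit's epochs into an m-shift start point."""
        ages = list(prev.model.shift_ages)
        lam, mu = list(prev.model.lam), list(prev.model.mu)
        grid = self._age_grid(None)
        for a in grid:
            if len(ages) == m:
                break
            if all(abs(a - b) > 1e-9 for b in ages):
                j = int(np.searchsorted(-np.asarray(ages or [np.inf]), -a))
                ages.insert(j, a)
                lam.insert(j, lam[min(j, len(lam) - 1)])
                mu.insert(j, mu[min(j, len(mu) - 1)])
        ages_t = tuple(sorted(ages, reverse=True))
        x0 = np.log(np.clip(np.array(lam + mu), _RATE_LO, _RATE_HI))
        return ages_t, x0

    def fit_sequence(self, max_shifts: int = 5, grid_step: float | None = None,
                     n_restarts: int = 3, seed: int = 0) -> list[ShiftFit]:
        """Fits for m = 0..max_shifts, chained so lnL is non-decreasing in m."""
        fits: list[ShiftFit] = []
        prev = None
        for m in range(max_shifts + 1):
            fit = self.fit(m, grid_step=grid_step, n_restarts=n_restarts,
                           seed=seed + m, prev=prev)
            fits.append(fit)
            prev = fit
        return fits


def select_shift_count(fits: list[ShiftFit], alpha: float = 0.05,
                       df: int = 3, tol: float = 1e-6) -> tuple[int, list[float]]:
    """Forward likelihood-ratio selection of the number of shifts.

    Accepts m+1 over m iff ``2 (lnL_{m+1} - lnL_m)`` exceeds the chi-square
    alpha-quantile with ``df`` degrees of freedom (3: two rates plus one shift
    age), stopping at the first failure. Returns the selected m and the
    per-step p-values.
    """
    if not fits:
        raise ValueError("no fits supplied")
    for i, f in enumerate(fits):
        if f.m != i:
            raise ValueError("fits must be ordered m = 0, 1, ...")
    pvals: list[float] = []
    selected = 0
    for i in range(len(fits) - 1):
        d = fits[i + 1].loglik - fits[i].loglik
        if d < -tol:
            raise ValueError(f"lnL decreased from m={i} to m={i + 1}: "
                             "nested models must not lose likelihood")
        stat = max(2.0 * d, 0.0)
        p = float(stats.chi2.sf(stat, df))
        pvals.append(p)
        if p < alpha and selected == i:
            selected = i + 1
    return selected, pvals
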
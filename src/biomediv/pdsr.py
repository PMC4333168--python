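"""PD ~ SR regression with optional spatial smooth, residuals, decile flags.

Phylogenetic diversity scales almost linearly with species richness; the
scientific signal is in the residuals — cells whose PD is unusually high or
low for their richness. The model is ordinary least squares of PD on a degree
1 or 2 polynomial of SR, optionally augmented with a low-rank Gaussian
radial-basis expansion of the cell coordinates (a generalized-additive-style
smooth capturing spatial autocorrelation) whose ridge penalty is selected by
generalized cross-validation (GCV). The top and bottom deciles of the
residuals flag cells with unusually high/low PD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PDSRModel", "PDSRResults", "flag_residual_deciles"]


def _farthest_point_centers(xy: np.ndarray, k: int) -> np.ndarray:
    """Deterministic space-filling subset of k rows of xy (farthest-point)."""
    centroid = xy.mean(axis=0)
    first = int(np.argmin(((xy - centroid) ** 2).sum(axis=1)))
    chosen = [first]
    d2 = ((xy - xy[first]) ** 2).sum(axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d2))
        if d2[nxt] <= 0:  # fewer distinct points than k
            break
        chosen.append(nxt)
        d2 = np.minimum(d2, ((xy - xy[nxt]) ** 2).sum(axis=1))
    return xy[chosen]


class PDSRModel:
    """Regression of Faith PD on species richness.

    Parameters
    ----------
    data : DataFrame
        Columns ``cell_id``, ``SR``, ``PD`` and, when ``spatial=True``,
        coordinates ``x`` and ``y``. Cells with SR = 0 are excluded from the
        fit (no community, PD trivially 0).
    degree : {1, 2}
        Polynomial degree in SR.
    spatial : bool
        Add the penalized radial-basis smooth of (x, y).
    n_centers : int
        Rank of the spatial basis (space-filling subset of the cells).
    """

    def __init__(self, data: pd.DataFrame, degree: int = 1, spatial: bool = False,
                 n_centers: int = 50,
                 penalty_grid: np.ndarray | None = None):
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        need = {"cell_id", "SR", "PD"} | ({"x", "y"} if spatial else set())
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        data = data.loc[data["SR"] > 0].reset_index(drop=True)
        if len(data) < 10:
            raise ValueError("need at least 10 cells with SR > 0")
        self.data = data
        self.degree = degree
        self.spatial = spatial
        self.n_centers = min(n_centers, len(data) - degree - 2)
        if spatial and self.n_centers < 3:
            raise ValueError("too few cells for the spatial basis; retry with spatial=False")
        self.penalty_grid = (np.logspace(-4, 6, 21) if penalty_grid is None
                             else np.asarray(penalty_grid, float))

    # -- design ------------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, int]:
        sr = self.data["SR"].to_numpy(float)
        if np.ptp(sr) == 0:
            raise ValueError("SR is constant across cells: singular design")
        cols = [np.ones_like(sr), sr]
        if self.degree == 2:
            cols.append(sr ** 2)
        n_poly = len(cols)
        if self.spatial:
            xy = self.data[["x", "y"]].to_numpy(float)
            centers = _farthest_point_centers(xy, self.n_centers)
            d = np.sqrt(((xy[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
            pairwise = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
            bw = np.median(pairwise[pairwise > 0]) if (pairwise > 0).any() else 1.0
            cols.extend(np.exp(-(d / bw) ** 2).T)
            self._centers, self._bandwidth = centers, bw
        return np.column_stack(cols), n_poly

    def fit(self) -> "PDSRResults":
        X, n_poly = self._design()
        y = self.data["PD"].to_numpy(float)
        n, p = X.shape
        if not self.spatial:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ beta
            edf = float(np.linalg.matrix_rank(X))
            if edf < p:
                raise ValueError("singular design matrix")
            penalty = 0.0
        else:
            # ridge on the RBF block only; GCV over the penalty grid
            pen_mask = np.zeros(p)
            pen_mask[n_poly:] = 1.0
            XtX, Xty = X.T @ X, X.T @ y
            best = None
            for lam in self.penalty_grid:
                A = XtX + lam * np.diag(pen_mask)
                try:
                    beta_l = np.linalg.solve(A, Xty)
                    trH = float(np.trace(np.linalg.solve(A, XtX)))
                except np.linalg.LinAlgError:
                    continue
                resid = y - X @ beta_l
                denom = max(n - trH, 1e-8)
                gcv = n * float(resid @ resid) / denom ** 2
                if best is None or gcv < best[0]:
                    best = (gcv, lam, beta_l, trH)
            if best is None:
                raise ValueError("spatial fit failed for every penalty")
            _, penalty, beta, edf = best
            fitted = X @ beta
        resid = y - fitted
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        sigma2 = rss / n
        loglik = -0.5 * n * (math.log(2 * math.pi * max(sigma2, 1e-300)) + 1)
        aic = 2 * (edf + 1) - 2 * loglik
        return PDSRResults(
            model=self, params=beta[:n_poly],
            smooth_coefs=beta[n_poly:] if self.spatial else None,
            penalty=penalty, edf=edf,
            fitted=pd.Series(fitted, index=self.data["cell_id"], name="fitted"),
            residuals=pd.Series(resid, index=self.data["cell_id"], name="residual"),
            r2=r2, rss=rss, aic=aic, nobs=n,
        )


@dataclass
class PDSRResults:
    """Fitted PD ~ SR relationship: coefficients, residuals, fit summary."""

    model: PDSRModel
    params: np.ndarray            # intercept, SR, (SR^2)
    smooth_coefs: np.ndarray | None
    penalty: float
    edf: float
    fitted: pd.Series
    residuals: pd.Series
    r2: float
    rss: float
    aic: float
    nobs: int

    param_names: tuple = field(init=False)

    def __post_init__(self):
        self.param_names = ("intercept", "SR", "SR^2")[: len(self.params)]

    def flag_deciles(self, fraction: float = 0.1) -> pd.DataFrame:
        return flag_residual_deciles(self, fraction)

    def summary(self) -> str:
        lines = [
            "PD ~ SR regression",
            f"  degree: {self.model.degree}   spatial smooth: {self.model.spatial}",
            f"  n cells: {self.nobs}   r^2: {self.r2:.4f}   AIC: {self.aic:.2f}",
        ]
        for name, b in zip(self.param_names, self.params):
            lines.append(f"  {name:>9s}: {b: .6g}")
        if self.smooth_coefs is not None:
            lines.append(f"  smooth: {len(self.smooth_coefs)} basis fns, "
                         f"ridge penalty {self.penalty:g}, edf {self.edf:.1f}")
        return "\n".join(lines)


def flag_residual_deciles(fit: PDSRResults, fraction: float = 0.1) -> pd.DataFrame:
    """Flag the top and bottom residual fractions (default deciles).

    Exactly ``ceil(fraction * n)`` cells are flagged ``high`` (largest
    residuals) and the same number ``low``; ties are broken by a stable sort
    on cell_id so flagging is deterministic.
    """
    if not (0.0 < fraction < 0.5):
        raise ValueError("fraction must be in (0, 0.5)")
    res = fit.residuals
    n = len(res)
    if n == 0:
        raise ValueError("no residuals to flag")
    k = math.ceil(fraction * n)
    df = pd.DataFrame({"cell_id": res.index, "residual": res.to_numpy()})
    df = df.sort_values("cell_id", kind="stable").reset_index(drop=True)
    order = np.argsort(df["residual"].to_numpy(), kind="stable")
    flags = np.array(["none"] * n, dtype=object)
    flags[order[:k]] = "low"
    flags[order[-k:]] = "high"
    df["flag"] = flags
    return df
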
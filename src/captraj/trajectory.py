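"""Left-flat sigmoidal trajectory regression against the CAP score.

The mean model for one region's response :math:`y` (raw or whole-brain
normalized volume) is

.. math::

    y = v_0 - \\delta\\, S\\!\\left(\\frac{\\max(c - \\tau, 0)}{s}\\right)
        + \\text{study offsets} + \\text{group offsets}
        + \\beta_{\\mathrm{ICV}}\\,(\\mathrm{ICV} - \\overline{\\mathrm{ICV}})
        + \\varepsilon,

where :math:`c` is the CAP score, :math:`\\tau` the changepoint ("CAP at
first slope change"), :math:`s > 0` the transition width, :math:`v_0` the
flat pre-changepoint level and :math:`\\delta \\ge 0` the total eventual
drop.  The ramp :math:`S(u) = 2/(1+e^{-u}) - 1` (equivalently
:math:`\\tanh(u/2)`) is exactly zero at :math:`u = 0`, so the curve is
*exactly* flat left of the changepoint — far-from-onset carriers and young
controls are modelled as constant — and declines sigmoidally to
:math:`v_0 - \\delta` thereafter.  The curve is continuous at :math:`\\tau`
and monotone non-increasing in CAP.

Fitting is least squares by profiling: conditional on :math:`(\\tau, s)`
the model is linear in :math:`(v_0, \\delta, \\text{covariates})`, so the
fitter sweeps a fixed :math:`\\tau` grid, searches :math:`s` within bounds,
and solves the inner linear problem in closed form.  The optimizer is
fully deterministic: identical data and options give bit-identical fits.
Scans are treated as independent at fit time; within-subject correlation
is honoured at inference time by the subject-block bootstrap in
:mod:`captraj.changepoint`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cap import CapConfig, assign_cap
from .cohort import make_response

# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the left-flat sigmoid mean curve.

    ``v0``: flat left level (response units); ``delta``: total eventual
    drop, >= 0; ``tau``: changepoint on the CAP axis; ``scale``: transition
    width in CAP units, > 0.
    """

    v0: float
    delta: float
    tau: float
    scale: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class CovariateCoefs:
    """Additive covariate effects; reference levels are exactly 0."""

    study_offsets: dict
    group_offsets: dict
    icv_slope: float = 0.0


@dataclass(frozen=True)
class SigmoidFit:
    params: SigmoidParams
    coefs: CovariateCoefs
    rss: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    converged: bool
    profile_grid: tuple  # ((tau, profiled rss), ...)
    fitted_values: np.ndarray
    residuals: np.ndarray

    def predict_curve(self, cap) -> np.ndarray:
        """Mean curve at reference covariate levels (trend line)."""
        return left_flat_sigmoid(cap, self.params)

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "coefs": dataclasses.asdict(self.coefs),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "profile_grid": [list(p) for p in self.profile_grid],
        }


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    coefs: CovariateCoefs
    rss: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    fitted_values: np.ndarray
    residuals: np.ndarray


@dataclass(frozen=True)
class ConstantFit:
    level: float
    coefs: CovariateCoefs
    rss: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    fitted_values: np.ndarray
    residuals: np.ndarray


@dataclass(frozen=True)
class ModelComparison:
    """Nested comparison of the three mean models on one dataset.

    ``stat`` is an F-like improvement statistic,
    ``(RSS_lin − RSS_sig)/RSS_sig × (n − p_sig)/(p_sig − p_lin)``; because
    the changepoint is estimated, its null distribution is obtained by
    bootstrap (:func:`captraj.changepoint.bootstrap_model_pvalue`), not
    from an F table.
    """

    sigmoid_rss: float
    linear_rss: float
    constant_rss: float
    stat: float
    sigmoid_preferred: bool
    p_value: Optional[float] = None


# --------------------------------------------------------------------------
# mean curve


def left_flat_sigmoid(cap, params: SigmoidParams):
    """Evaluate the left-flat sigmoid mean curve at CAP value(s) ``cap``.

    Returns ``v0`` exactly for ``cap <= tau``; for ``cap > tau`` returns
    ``v0 - delta * S((cap - tau)/scale)`` with ``S(u) = 2/(1+exp(-u)) - 1``.
    """
    cap = np.asarray(cap, dtype=float)
    u = np.maximum(cap - params.tau, 0.0) / params.scale
    out = params.v0 - params.delta * np.tanh(0.5 * u)  # tanh(u/2) == 2/(1+e^-u)-1
    return float(out) if out.ndim == 0 else out


def _ramp(cap: np.ndarray, tau, scale) -> np.ndarray:
    return np.tanh(0.5 * np.maximum(cap - tau, 0.0) / scale)


# --------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the profile fit.

    ``tau_grid_step``: spacing of the changepoint grid in CAP units; the
    grid spans the 5th–95th percentile of observed CAP, snapped to
    multiples of the step.  ``scale_bounds`` defaults to
    ``(tau_grid_step/2, observed CAP span)``.  ``n_scale_grid`` controls the
    coarse geometric scale grid refined by a bounded 1-D search.
    """

    tau_grid_step: float = 5.0
    tau_grid: Optional[tuple] = None
    scale_bounds: Optional[tuple] = None
    n_scale_grid: int = 25
    n_refine: int = 5
    min_obs: int = 20
    alpha: float = 0.05


@dataclass(frozen=True)
class FitDataset:
    """Fit-ready arrays for one ROI: CAP, response, covariate design."""

    cap: np.ndarray
    y: np.ndarray
    Z: np.ndarray
    colnames: tuple
    subject_ids: np.ndarray
    roi: str
    normalize_wbv: bool
    studies: tuple
    groups: tuple

    @property
    def n(self) -> int:
        return len(self.y)

    def with_response(self, y: np.ndarray) -> "FitDataset":
        return dataclasses.replace(self, y=np.asarray(y, dtype=float))


def design_response(
    cohort: pd.DataFrame,
    roi: str,
    normalize_wbv: bool = False,
    cap_config: Optional[CapConfig] = None,
    include_icv: bool = True,
    log_response: bool = False,
    min_obs: int = 20,
) -> FitDataset:
    """Build the fit-ready dataset for one ROI.

    CAP scores are assigned via ``cap_config`` when given (this also applies
    the control scheme and under-40 filter); otherwise a filled ``cap``
    column is required.  Covariates are reference-coded with the
    alphabetically first study/group as reference; ICV is mean-centred.
    """
    df = cohort
    if cap_config is not None:
        df = assign_cap(df, cap_config)
    if "cap" not in df.columns or df["cap"].isna().any():
        raise ValueError("cohort has no complete 'cap' column; pass cap_config")
    if len(df) < min_obs:
        raise ValueError(f"only {len(df)} observations; minimum is {min_obs}")

    y = make_response(df, roi, normalize_wbv)
    if log_response:
        y = np.log(y)
    cap = df["cap"].to_numpy(dtype=float)

    cols = [np.ones(len(df))]
    names = ["intercept"]
    studies = tuple(sorted(df["study"].unique()))
    for s in studies[1:]:
        cols.append(df["study"].eq(s).to_numpy(dtype=float))
        names.append(f"study_{s}")
    groups = tuple(sorted(df["group"].unique()))
    for g in groups[1:]:
        cols.append(df["group"].eq(g).to_numpy(dtype=float))
        names.append(f"group_{g}")
    if include_icv:
        icv = df["icv"].to_numpy(dtype=float)
        cols.append(icv - icv.mean())
        names.append("icv_centered")

    Z = np.column_stack(cols)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify offending columns from the QR diagonal
        _, R = np.linalg.qr(Z)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"degenerate (collinear) design; offending columns: {bad}")

    return FitDataset(
        cap=cap,
        y=np.asarray(y, dtype=float),
        Z=Z,
        colnames=tuple(names),
        subject_ids=df["subject_id"].to_numpy(),
        roi=roi,
        normalize_wbv=normalize_wbv,
        studies=studies,
        groups=groups,
    )


# --------------------------------------------------------------------------
# fitting


def _ic(rss: float, n: int, n_params: int) -> tuple[float, float]:
    if rss <= 0:
        return -np.inf, -np.inf
    ll_term = n * np.log(rss / n)
    k = n_params + 1  # + error variance
    return ll_term + 2 * k, ll_term + np.log(n) * k


def _extract_coefs(dataset: FitDataset, beta_z: np.ndarray) -> CovariateCoefs:
    lookup = dict(zip(dataset.colnames, beta_z))
    study = {s: 0.0 for s in dataset.studies}
    group = {g: 0.0 for g in dataset.groups}
    for s in dataset.studies[1:]:
        study[s] = float(lookup[f"study_{s}"])
    for g in dataset.groups[1:]:
        group[g] = float(lookup[f"group_{g}"])
    return CovariateCoefs(
        study_offsets=study,
        group_offsets=group,
        icv_slope=float(lookup.get("icv_centered", 0.0)),
    )


class ProfileFitter:
    """Deterministic profile least-squares fitter for one design.

    Precomputes the orthonormal basis of the covariate block and the
    projected ramp regressors for every (tau, scale) grid candidate, so
    refitting with a new response vector — the inner loop of the bootstrap —
    costs one matrix–vector product.
    """

    def __init__(self, dataset: FitDataset, options: FitOptions = FitOptions()):
        self.dataset = dataset
        self.options = options
        cap = dataset.cap
        span = float(cap.max() - cap.min())
        step = options.tau_grid_step
        if span <= step:
            raise ValueError(
                f"CAP span {span:.3g} not wider than tau grid step {step:.3g}"
            )

        if options.tau_grid is not None:
            self.tau_grid = np.asarray(options.tau_grid, dtype=float)
        else:
            lo, hi = np.percentile(cap, [5.0, 95.0])
            start = np.ceil(lo / step) * step
            stop = np.floor(hi / step) * step
            if stop <= start:
                start, stop = np.floor(lo / step) * step, np.ceil(hi / step) * step
            self.tau_grid = np.arange(start, stop + 0.5 * step, step)

        if options.scale_bounds is not None:
            self.scale_bounds = (float(options.scale_bounds[0]), float(options.scale_bounds[1]))
        else:
            self.scale_bounds = (max(step / 2.0, 1e-6), max(span, step))
        self.scale_grid = np.geomspace(
            self.scale_bounds[0], self.scale_bounds[1], options.n_scale_grid
        )

        Z = dataset.Z
        self.Q, _ = np.linalg.qr(Z)

        T, S = len(self.tau_grid), len(self.scale_grid)
        # candidate ramp regressors, residualized against the covariate block
        R = np.tanh(
            0.5
            * np.maximum(cap[None, :] - self.tau_grid[:, None], 0.0)[:, None, :]
            / self.scale_grid[None, :, None]
        ).reshape(T * S, -1)
        self.Rperp = R - (R @ self.Q) @ self.Q.T
        self.norms2 = np.einsum("ij,ij->i", self.Rperp, self.Rperp)
        self._shape = (T, S)

    # -- inner linear solves ------------------------------------------------

    def _project(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        y_perp = y - self.Q @ (self.Q.T @ y)
        return y_perp, float(y_perp @ y_perp)

    def _rss_grid(self, y_perp: np.ndarray, yty: float) -> np.ndarray:
        dots = self.Rperp @ y_perp
        neg = np.minimum(dots, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(self.norms2 > 1e-300, neg * neg / self.norms2, 0.0)
        return (yty - gain).reshape(self._shape)

    def _rss_at(self, tau: float, scale: float, y_perp: np.ndarray, yty: float) -> float:
        r = _ramp(self.dataset.cap, tau, scale)
        r_perp = r - self.Q @ (self.Q.T @ r)
        n2 = float(r_perp @ r_perp)
        if n2 <= 1e-300:
            return yty
        dot = float(r_perp @ y_perp)
        return yty - min(dot, 0.0) ** 2 / n2

    # -- public fits --------------------------------------------------------

    def fit(self, y: Optional[np.ndarray] = None) -> SigmoidFit:
        """Profile fit of the left-flat sigmoid; deterministic.

        Ties on RSS are broken toward the smallest changepoint; the fit is
        flagged non-converged when the optimum sits on the tau-grid
        boundary or the drop degenerates to zero.
        """
        ds = self.dataset
        y = ds.y if y is None else np.asarray(y, dtype=float)
        y_perp, yty = self._project(y)
        rss_grid = self._rss_grid(y_perp, yty)
        profile = rss_grid.min(axis=1)

        # refine the most promising tau candidates with a bounded 1-D
        # search on scale between the neighbouring grid scales
        order = np.argsort(profile, kind="stable")[: self.options.n_refine]
        best = None
        for ti in order:
            tau = float(self.tau_grid[ti])
            sj = int(np.argmin(rss_grid[ti]))
            lo = self.scale_grid[max(sj - 1, 0)]
            hi = self.scale_grid[min(sj + 1, len(self.scale_grid) - 1)]
            cand_rss = float(rss_grid[ti, sj])
            cand_scale = float(self.scale_grid[sj])
            if hi > lo:
                res = minimize_scalar(
                    lambda s: self._rss_at(tau, s, y_perp, yty),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-10 * (self.scale_bounds[1] - self.scale_bounds[0] + 1.0)},
                )
                if res.fun < cand_rss:
                    cand_rss, cand_scale = float(res.fun), float(res.x)
            key = (cand_rss, tau)
            if best is None or key < best[0]:
                best = (key, tau, cand_scale, ti)
        (rss_best, _), tau_hat, scale_hat, ti_best = best

        # final full linear solve at the selected (tau, scale)
        r = _ramp(ds.cap, tau_hat, scale_hat)
        X = np.column_stack([ds.Z, r])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        delta = -float(beta[-1])
        if delta < 0:
            beta_z, *_ = np.linalg.lstsq(ds.Z, y, rcond=None)
            delta = 0.0
            fitted = ds.Z @ beta_z
        else:
            beta_z = beta[:-1]
            fitted = X @ beta
        residuals = y - fitted
        rss = float(residuals @ residuals)

        converged = bool(delta > 0 and 0 < int(ti_best) < len(self.tau_grid) - 1)
        n_params = ds.Z.shape[1] + 3  # + delta, tau, scale
        aic, bic = _ic(rss, ds.n, n_params)
        profile_out = [(float(t), float(p)) for t, p in zip(self.tau_grid, profile)]
        profile_out[ti_best] = (tau_hat, rss)

        return SigmoidFit(
            params=SigmoidParams(
                v0=float(beta_z[0]), delta=delta, tau=tau_hat, scale=scale_hat
            ),
            coefs=_extract_coefs(ds, beta_z),
            rss=rss,
            n_obs=ds.n,
            n_params=n_params,
            aic=aic,
            bic=bic,
            converged=converged,
            profile_grid=tuple(profile_out),
            fitted_values=fitted,
            residuals=residuals,
        )

    def fit_linear(self, y: Optional[np.ndarray] = None) -> LinearFit:
        ds = self.dataset
        y = ds.y if y is None else np.asarray(y, dtype=float)
        X = np.column_stack([ds.Z, ds.cap])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        residuals = y - fitted
        rss = float(residuals @ residuals)
        n_params = ds.Z.shape[1] + 1
        aic, bic = _ic(rss, ds.n, n_params)
        return LinearFit(
            slope=float(beta[-1]),
            intercept=float(beta[0]),
            coefs=_extract_coefs(ds, beta[:-1]),
            rss=rss,
            n_obs=ds.n,
            n_params=n_params,
            aic=aic,
            bic=bic,
            fitted_values=fitted,
            residuals=residuals,
        )

    def fit_constant(self, y: Optional[np.ndarray] = None) -> ConstantFit:
        ds = self.dataset
        y = ds.y if y is None else np.asarray(y, dtype=float)
        beta, *_ = np.linalg.lstsq(ds.Z, y, rcond=None)
        fitted = ds.Z @ beta
        residuals = y - fitted
        rss = float(residuals @ residuals)
        n_params = ds.Z.shape[1]
        aic, bic = _ic(rss, ds.n, n_params)
        return ConstantFit(
            level=float(beta[0]),
            coefs=_extract_coefs(ds, beta),
            rss=rss,
            n_obs=ds.n,
            n_params=n_params,
            aic=aic,
            bic=bic,
            fitted_values=fitted,
            residuals=residuals,
        )


def fit_sigmoid(dataset: FitDataset, options: FitOptions = FitOptions()) -> SigmoidFit:
    """Fit the left-flat sigmoid model (convenience wrapper)."""
    return ProfileFitter(dataset, options).fit()


def fit_linear(dataset: FitDataset, options: FitOptions = FitOptions()) -> LinearFit:
    """Ordinary least squares with the same covariates plus a CAP slope."""
    return ProfileFitter(dataset, options).fit_linear()


def fit_constant(dataset: FitDataset, options: FitOptions = FitOptions()) -> ConstantFit:
    """Covariates-only (flat trajectory) least squares fit."""
    return ProfileFitter(dataset, options).fit_constant()


def improvement_stat(
    linear_rss: float, sigmoid_rss: float, n: int, p_sig: int, p_lin: int
) -> float:
    if sigmoid_rss <= 0:
        return np.inf if linear_rss > 0 else 0.0
    return (linear_rss - sigmoid_rss) / sigmoid_rss * (n - p_sig) / (p_sig - p_lin)


def compare_models(
    sigmoid: SigmoidFit,
    linear: LinearFit,
    constant: ConstantFit,
    p_value: Optional[float] = None,
    alpha: float = 0.05,
) -> ModelComparison:
    """Compare the sigmoid fit against its nested linear and constant rivals.

    Preference is decided by the bootstrap p-value when one is supplied,
    otherwise by BIC.
    """
    if not (sigmoid.n_obs == linear.n_obs == constant.n_obs):
        raise ValueError("model fits come from datasets of different sizes")
    stat = improvement_stat(
        linear.rss, sigmoid.rss, sigmoid.n_obs, sigmoid.n_params, linear.n_params
    )
    if p_value is not None:
        preferred = p_value < alpha
    else:
        preferred = sigmoid.bic < linear.bic
    return ModelComparison(
        sigmoid_rss=sigmoid.rss,
        linear_rss=linear.rss,
        constant_rss=constant.rss,
        stat=stat,
        sigmoid_preferred=bool(preferred),
        p_value=p_value,
    )


def save_fit(fit: SigmoidFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
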
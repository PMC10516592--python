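"""Semi-parametric bootstrap inference for the trajectory changepoint.

Uncertainty is assessed by a residual bootstrap around the fitted
parametric mean: fitted values are kept at the original design points and
residuals are resampled, so the scheme is semi-parametric (parametric mean,
non-parametric errors).  Residuals are resampled in *subject blocks* — a
subject's whole residual vector is replaced by that of a randomly drawn
subject with the same number of scans — which preserves any within-subject
correlation that the point fit, treating scans as independent, ignores.

Two quantities are produced per region:

* the SD of the changepoint estimate (bootstrap around the sigmoid fit);
* a p-value for sigmoid-over-linear, with null datasets generated from the
  fitted *linear* model and the observed improvement statistic referred to
  its null distribution under the add-one convention
  ``p = (r + 1)/(B + 1)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory import (
    FitDataset,
    FitOptions,
    ProfileFitter,
    SigmoidFit,
    compare_models,
    improvement_stat,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapOptions:
    """Settings for the semi-parametric bootstrap.

    ``resample_unit="subject"`` moves whole per-subject residual vectors
    (the default, honouring repeated scans); ``"scan"`` resamples residuals
    independently.  ``null_model`` selects the mean used to generate null
    datasets for the model-comparison p-value.
    """

    n_reps: int = 999
    resample_unit: str = "subject"
    seed: int = 0
    alpha: float = 0.05
    null_model: str = "linear"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.resample_unit not in ("subject", "scan"):
            raise ValueError("resample_unit must be 'subject' or 'scan'")
        if self.null_model not in ("linear", "constant"):
            raise ValueError("null_model must be 'linear' or 'constant'")


@dataclass(frozen=True)
class ChangepointResult:
    """Changepoint estimate and bootstrap inference for one region."""

    roi: str
    tau_hat: float
    tau_sd: float
    p_value: float
    n_effective_reps: int
    sigmoid_preferred: bool


class _BlockResampler:
    """Resamples residual vectors in subject blocks of equal length."""

    def __init__(self, subject_ids: np.ndarray, unit: str):
        self.unit = unit
        self.n = len(subject_ids)
        if unit == "subject":
            order = {}
            for i, sid in enumerate(subject_ids):
                order.setdefault(sid, []).append(i)
            self.blocks = [np.asarray(ix) for ix in order.values()]
            self.by_size: dict[int, list[np.ndarray]] = {}
            for b in self.blocks:
                self.by_size.setdefault(len(b), []).append(b)

    def resample(self, residuals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.unit == "scan":
            return residuals[rng.integers(0, self.n, size=self.n)]
        out = np.empty_like(residuals)
        for block in self.blocks:
            donors = self.by_size[len(block)]
            donor = donors[rng.integers(0, len(donors))]
            out[block] = residuals[donor]
        return out


@dataclass(frozen=True)
class TauBootstrap:
    tau_sd: float
    taus: np.ndarray
    n_effective_reps: int
    unstable: bool  # > 20% of replicates failed to converge


def bootstrap_tau_sd(
    dataset: FitDataset,
    fit: SigmoidFit,
    options: BootstrapOptions = BootstrapOptions(),
    fitter: Optional[ProfileFitter] = None,
    fit_options: FitOptions = FitOptions(),
) -> TauBootstrap:
    """Bootstrap SD of the changepoint estimate.

    Each replicate re-attaches subject-block resampled residuals to the
    sigmoid fitted values and refits; non-converged replicates (grid
    boundary or degenerate drop) are dropped and counted.
    """
    if fitter is None:
        fitter = ProfileFitter(dataset, fit_options)
    rng = np.random.default_rng(options.seed)
    resampler = _BlockResampler(dataset.subject_ids, options.resample_unit)

    taus = []
    for _ in range(options.n_reps):
        y_star = fit.fitted_values + resampler.resample(fit.residuals, rng)
        refit = fitter.fit(y_star)
        if refit.converged:
            taus.append(refit.params.tau)
    taus = np.asarray(taus)
    n_eff = len(taus)
    unstable = n_eff < 0.8 * options.n_reps
    if unstable:
        logger.warning(
            "tau bootstrap: only %d/%d replicates converged", n_eff, options.n_reps
        )
    tau_sd = float(np.std(taus, ddof=1)) if n_eff > 1 else float("nan")
    return TauBootstrap(tau_sd=tau_sd, taus=taus, n_effective_reps=n_eff, unstable=unstable)


@dataclass(frozen=True)
class ModelPValue:
    p_value: float
    stat_observed: float
    null_stats: np.ndarray
    n_effective_reps: int


def bootstrap_model_pvalue(
    dataset: FitDataset,
    options: BootstrapOptions = BootstrapOptions(),
    fitter: Optional[ProfileFitter] = None,
    fit_options: FitOptions = FitOptions(),
) -> ModelPValue:
    """Bootstrap p-value for sigmoid-over-linear improvement.

    Null datasets are the fitted null-model mean (linear by default) plus
    subject-block resampled null-model residuals.  Replicate sigmoid fits
    that land on the grid boundary still yield a valid RSS and are kept, so
    the null distribution is not truncated.
    """
    if fitter is None:
        fitter = ProfileFitter(dataset, fit_options)
    sig = fitter.fit()
    lin = fitter.fit_linear()
    null_fit = lin if options.null_model == "linear" else fitter.fit_constant()
    stat_obs = improvement_stat(lin.rss, sig.rss, dataset.n, sig.n_params, lin.n_params)

    rng = np.random.default_rng(options.seed)
    resampler = _BlockResampler(dataset.subject_ids, options.resample_unit)
    null_stats = np.empty(options.n_reps)
    for b in range(options.n_reps):
        y_star = null_fit.fitted_values + resampler.resample(null_fit.residuals, rng)
        sig_b = fitter.fit(y_star)
        lin_b = fitter.fit_linear(y_star)
        null_stats[b] = improvement_stat(
            lin_b.rss, sig_b.rss, dataset.n, sig_b.n_params, lin_b.n_params
        )
    exceed = int(np.sum(null_stats >= stat_obs))
    p = (exceed + 1) / (options.n_reps + 1)
    return ModelPValue(
        p_value=p,
        stat_observed=stat_obs,
        null_stats=null_stats,
        n_effective_reps=options.n_reps,
    )


def run_changepoint(
    dataset: FitDataset,
    options: BootstrapOptions = BootstrapOptions(),
    fit_options: FitOptions = FitOptions(),
) -> ChangepointResult:
    """Full changepoint inference for one region.

    Deterministic given (dataset, options): the tau bootstrap and the null
    bootstrap use independent streams spawned from ``options.seed``.
    """
    fitter = ProfileFitter(dataset, fit_options)
    fit = fitter.fit()
    seeds = np.random.SeedSequence(options.seed).generate_state(2) % (2**31)
    tau_boot = bootstrap_tau_sd(
        dataset, fit, dataclasses.replace(options, seed=int(seeds[0])), fitter=fitter
    )
    pval = bootstrap_model_pvalue(
        dataset, dataclasses.replace(options, seed=int(seeds[1])), fitter=fitter
    )
    return ChangepointResult(
        roi=dataset.roi,
        tau_hat=fit.params.tau,
        tau_sd=tau_boot.tau_sd,
        p_value=pval.p_value,
        n_effective_reps=tau_boot.n_effective_reps,
        sigmoid_preferred=pval.p_value < options.alpha,
    )


def changepoint_table(results: Sequence[ChangepointResult]) -> pd.DataFrame:
    """Ranked changepoint table.

    Only regions where the sigmoid beat the linear model are listed, sorted
    by ascending changepoint (earliest-affected first); ties broken by SD
    then name.
    """
    rows = [dataclasses.asdict(r) for r in results if r.sigmoid_preferred]
    df = pd.DataFrame(
        rows,
        columns=[
            "roi",
            "tau_hat",
            "tau_sd",
            "p_value",
            "n_effective_reps",
            "sigmoid_preferred",
        ],
    )
    if len(df):
        df = df.sort_values(["tau_hat", "tau_sd", "roi"], kind="stable").reset_index(
            drop=True
        )
    return df


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
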
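"""Simulation studies validating the estimator and its bootstrap inference.

Each study generates cohorts from the synthetic generator under stated
conditions, runs the full analysis path, and measures a calibration or
recovery quantity: parameter recovery error, type-I error of the
sigmoid-vs-linear bootstrap test, coverage of changepoint intervals, and
recovery of the regional changepoint ordering.  They are the package's own
evidence that the machinery works at realistic signal-to-noise; the same
functions back the reproduction script and the test suite.

All studies are deterministic given their base seed: per-replicate seeds
are ``base_seed + k`` for the generator and an offset stream for the
bootstrap.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

from .cap import CapConfig, assign_cap
from .changepoint import BootstrapOptions, bootstrap_model_pvalue, bootstrap_tau_sd
from .cohort import BASAL_GANGLIA_ROIS
from .pipeline import RunConfig, analyze_cohort
from .simulate import (
    CohortScenario,
    default_hd_scenario,
    generate_cohort,
    linear_truth_scenario,
)
from .trajectory import (
    FitDataset,
    FitOptions,
    ProfileFitter,
    SigmoidParams,
    design_response,
    _ramp,
)

#: Single-region study truth: 30% eventual drop from a putamen-sized flat
#: level, changepoint at CAP 300 (on the default grid), width 60.
PROBE_TRUTH = SigmoidParams(v0=8000.0, delta=2400.0, tau=300.0, scale=60.0)


def probe_scenario(seed: int, n_carriers: int = 150, n_controls: int = 60,
                   noise: float = 0.03, truth: SigmoidParams = PROBE_TRUTH,
                   **kw) -> CohortScenario:
    """Default-structure scenario carrying one probe region."""
    defaults = dict(
        n_carriers=n_carriers,
        n_controls=n_controls,
        noise_sd_fraction=noise,
        artefact_rate=0.0,
        seed=seed,
        roi_truths={"probe": truth},
    )
    defaults.update(kw)
    return default_hd_scenario(**defaults)


def _probe_dataset(seed: int, **kw) -> FitDataset:
    cohort = generate_cohort(probe_scenario(seed=seed, **kw))
    return design_response(assign_cap(cohort, CapConfig()), "probe")


# --------------------------------------------------------------------------
# estimator checks


def zero_noise_recovery(seed: int = 0) -> dict:
    """Relative parameter errors when data lie exactly on the true curve.

    ICV coupling is off so the flat level is identified without a centring
    offset; study and group batch effects stay on and must be absorbed by
    the covariates.
    """
    ds = _probe_dataset(seed, n_carriers=200, n_controls=80, noise=0.0, icv_coupling=0.0)
    fit = ProfileFitter(ds).fit()
    t, p = PROBE_TRUTH, fit.params
    return {
        "v0": abs(p.v0 - t.v0) / t.v0,
        "delta": abs(p.delta - t.delta) / t.delta,
        "tau": abs(p.tau - t.tau) / t.tau,
        "scale": abs(p.scale - t.scale) / t.scale,
        "n": ds.n,
    }


def brute_force_profile_rss(ds: FitDataset, options: FitOptions = FitOptions()) -> float:
    """Reference profile minimum by naive exhaustive search.

    For every changepoint on the grid, builds the full design matrix and
    solves least squares directly (no precomputation, no projection
    shortcut), minimizing over the transition width with a bounded search
    from a dense width grid.  Slow by construction; used to cross-check the
    production fitter.
    """
    fitter = ProfileFitter(ds, options)  # reuse only the grid definitions

    def rss_full(tau: float, scale: float) -> float:
        X = np.column_stack([ds.Z, _ramp(ds.cap, tau, scale)])
        beta, *_ = np.linalg.lstsq(X, ds.y, rcond=None)
        if -beta[-1] < 0:  # drop constrained to be non-negative
            beta, *_ = np.linalg.lstsq(ds.Z, ds.y, rcond=None)
            resid = ds.y - ds.Z @ beta
        else:
            resid = ds.y - X @ beta
        return float(resid @ resid)

    lo, hi = fitter.scale_bounds
    dense_scales = np.geomspace(lo, hi, 200)
    best = np.inf
    for tau in fitter.tau_grid:
        vals = [rss_full(tau, s) for s in dense_scales]
        j = int(np.argmin(vals))
        blo, bhi = dense_scales[max(j - 1, 0)], dense_scales[min(j + 1, len(dense_scales) - 1)]
        res = minimize_scalar(
            lambda s: rss_full(tau, s), bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-10 * (hi - lo + 1.0)},
        )
        best = min(best, vals[j], float(res.fun))
    return best


def oracle_gap(seed: int = 0, n_carriers: int = 18, n_controls: int = 8) -> dict:
    """Relative RSS gap between the production fitter and brute force."""
    ds = _probe_dataset(seed, n_carriers=n_carriers, n_controls=n_controls)
    fit = ProfileFitter(ds).fit()
    oracle = brute_force_profile_rss(ds)
    return {"gap": abs(fit.rss - oracle) / oracle, "n": ds.n}


def tau_recovery_study(
    n_seeds: int = 20,
    n_carriers: int = 300,
    n_controls: int = 100,
    noise: float = 0.03,
    base_seed: int = 0,
) -> dict:
    """Median absolute changepoint error over simulation replicates."""
    errors = []
    for k in range(n_seeds):
        ds = _probe_dataset(base_seed + k, n_carriers=n_carriers,
                            n_controls=n_controls, noise=noise)
        fit = ProfileFitter(ds).fit()
        errors.append(abs(fit.params.tau - PROBE_TRUTH.tau))
    return {
        "median_abs_error": float(np.median(errors)),
        "errors": errors,
        "n": n_seeds,
    }


# --------------------------------------------------------------------------
# bootstrap calibration


def type_one_error_study(
    n_datasets: int = 200,
    n_reps: int = 199,
    n_carriers: int = 100,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Rejection rate of the sigmoid-vs-linear test under a linear truth.

    Carriers-only cohorts with an exactly linear declining trajectory, so
    the null model is correctly specified; the reported rate should sit
    near ``alpha``.
    """
    rejections = 0
    for k in range(n_datasets):
        cohort = generate_cohort(linear_truth_scenario(n_carriers=n_carriers,
                                                       seed=base_seed + k))
        capped = assign_cap(cohort, CapConfig(control_scheme="exclude"))
        ds = design_response(capped, "roi_linear")
        fitter = ProfileFitter(ds)
        res = bootstrap_model_pvalue(
            ds, BootstrapOptions(n_reps=n_reps, seed=base_seed + 70000 + k),
            fitter=fitter,
        )
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_datasets, "n": n_datasets}


def coverage_study(
    n_sims: int = 100,
    n_reps: int = 199,
    n_carriers: int = 150,
    n_controls: int = 60,
    noise: float = 0.03,
    base_seed: int = 0,
) -> dict:
    """Coverage of ``tau_hat ± 2·tau_sd`` for the true changepoint."""
    covered = 0
    for k in range(n_sims):
        ds = _probe_dataset(base_seed + k, n_carriers=n_carriers,
                            n_controls=n_controls, noise=noise)
        fitter = ProfileFitter(ds)
        fit = fitter.fit()
        boot = bootstrap_tau_sd(
            ds, fit, BootstrapOptions(n_reps=n_reps, seed=base_seed + 80000 + k),
            fitter=fitter,
        )
        covered += abs(fit.params.tau - PROBE_TRUTH.tau) <= 2.0 * boot.tau_sd
    return {"coverage": covered / n_sims, "n": n_sims}


# --------------------------------------------------------------------------
# ordering of regional changepoints


def staggered_truths(n_rois: int = 6, tau0: float = 200.0, spacing: float = 50.0) -> dict:
    return {
        f"roi{i}": SigmoidParams(8000.0, 2400.0, tau0 + spacing * i, 60.0)
        for i in range(n_rois)
    }


def ordering_study(
    n_seeds: int = 20,
    n_carriers: int = 200,
    n_controls: int = 80,
    base_seed: int = 0,
) -> dict:
    """Spearman correlation between true and recovered changepoint order."""
    truths = staggered_truths()
    true_taus = [truths[r].tau for r in sorted(truths)]
    rhos = []
    for k in range(n_seeds):
        sc = default_hd_scenario(
            n_carriers=n_carriers, n_controls=n_controls, artefact_rate=0.0,
            seed=base_seed + k, roi_truths=truths,
        )
        res = analyze_cohort(generate_cohort(sc), RunConfig())
        est = [res["analyses"][r].result.tau_hat for r in sorted(truths)]
        rhos.append(float(spearmanr(est, true_taus).statistic))
    return {"median_rho": float(np.median(rhos)), "rhos": rhos, "n": n_seeds}


def basal_ganglia_first_study(
    n_seeds: int = 20,
    n_carriers: int = 200,
    n_controls: int = 80,
    base_seed: int = 0,
) -> dict:
    """How often the earliest tabulated changepoint is a basal-ganglia region."""
    hits = 0
    for k in range(n_seeds):
        sc = default_hd_scenario(n_carriers=n_carriers, n_controls=n_controls,
                                 seed=base_seed + k)
        res = analyze_cohort(generate_cohort(sc), RunConfig())
        table = res["table"]
        hits += len(table) > 0 and table["roi"].iloc[0] in BASAL_GANGLIA_ROIS
    return {"fraction_first": hits / n_seeds, "n": n_seeds}
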
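"""End-to-end orchestration: fit every region, tabulate changepoints,
export trend lines and per-subject spaghetti data.

These functions are the library behind the command-line interface; they
take and return plain DataFrames/dataclasses so they are equally usable
from scripts and notebooks.  All outputs are deterministic given the input
table, configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cap import CapConfig, assign_cap
from .changepoint import (
    BootstrapOptions,
    ChangepointResult,
    bootstrap_model_pvalue,
    bootstrap_tau_sd,
    changepoint_table,
)
from .cohort import (
    ExclusionRules,
    apply_exclusions,
    exclusion_report,
    make_response,
    roi_columns,
)
from .trajectory import (
    FitOptions,
    ProfileFitter,
    SigmoidFit,
    compare_models,
    design_response,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run (serialized for provenance)."""

    cap: CapConfig = field(default_factory=CapConfig)
    rois: Optional[tuple] = None  # None = every ROI column in the table
    normalize_wbv: bool = False
    include_icv: bool = True
    fit: FitOptions = field(default_factory=FitOptions)
    bootstrap: Optional[BootstrapOptions] = None
    exclusions: ExclusionRules = field(default_factory=ExclusionRules)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RoiAnalysis:
    roi: str
    fit: SigmoidFit
    comparison: "object"
    result: ChangepointResult


def analyze_cohort(cohort: pd.DataFrame, config: RunConfig = RunConfig()) -> dict:
    """Fit every requested region and run changepoint inference.

    Returns ``{"analyses": {roi: RoiAnalysis}, "table": DataFrame,
    "exclusion_report": dict, "cohort": post-QC cohort with CAP}``.
    When ``config.bootstrap`` is None, preference falls back to BIC and the
    bootstrap quantities are NaN.
    """
    t0 = time.perf_counter()
    kept, excluded = apply_exclusions(cohort, config.exclusions)
    report = exclusion_report(kept, excluded)
    capped = assign_cap(kept, config.cap)
    rois = list(config.rois) if config.rois is not None else roi_columns(capped)

    analyses = {}
    results = []
    for roi in rois:
        ds = design_response(
            capped,
            roi,
            normalize_wbv=config.normalize_wbv,
            include_icv=config.include_icv,
            min_obs=config.fit.min_obs,
        )
        fitter = ProfileFitter(ds, config.fit)
        fit = fitter.fit()
        lin = fitter.fit_linear()
        const = fitter.fit_constant()
        if config.bootstrap is not None:
            seeds = np.random.SeedSequence(
                [config.bootstrap.seed, _stable_hash(roi)]
            ).generate_state(2) % (2**31)
            tau_boot = bootstrap_tau_sd(
                ds,
                fit,
                dataclasses.replace(config.bootstrap, seed=int(seeds[0])),
                fitter=fitter,
            )
            pval = bootstrap_model_pvalue(
                ds,
                dataclasses.replace(config.bootstrap, seed=int(seeds[1])),
                fitter=fitter,
            )
            comparison = compare_models(
                fit, lin, const, p_value=pval.p_value, alpha=config.bootstrap.alpha
            )
            result = ChangepointResult(
                roi=roi,
                tau_hat=fit.params.tau,
                tau_sd=tau_boot.tau_sd,
                p_value=pval.p_value,
                n_effective_reps=tau_boot.n_effective_reps,
                sigmoid_preferred=comparison.sigmoid_preferred,
            )
        else:
            comparison = compare_models(fit, lin, const)
            result = ChangepointResult(
                roi=roi,
                tau_hat=fit.params.tau,
                tau_sd=float("nan"),
                p_value=float("nan"),
                n_effective_reps=0,
                sigmoid_preferred=comparison.sigmoid_preferred,
            )
        analyses[roi] = RoiAnalysis(roi=roi, fit=fit, comparison=comparison, result=result)
        results.append(result)
        logger.info(
            "%s: tau=%.1f rss=%.4g preferred=%s (%.2fs elapsed)",
            roi,
            fit.params.tau,
            fit.rss,
            result.sigmoid_preferred,
            time.perf_counter() - t0,
        )

    return {
        "analyses": analyses,
        "table": changepoint_table(results),
        "exclusion_report": report,
        "cohort": capped,
    }


def _stable_hash(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def trend_lines(analyses: dict, n_points: int = 101) -> pd.DataFrame:
    """Fitted mean curves on a CAP grid at reference covariate levels.

    The machine-readable analogue of a summary trend-line figure: one row
    per (roi, cap) with the left-flat sigmoid evaluated at the fitted
    parameters.
    """
    frames = []
    for roi, a in analyses.items():
        prof = np.asarray(a.fit.profile_grid)
        lo, hi = prof[0, 0], prof[-1, 0]
        grid = np.linspace(lo, hi, n_points)
        frames.append(
            pd.DataFrame({"roi": roi, "cap": grid, "fitted": a.fit.predict_curve(grid)})
        )
    return pd.concat(frames, ignore_index=True)


def spaghetti_data(
    cohort: pd.DataFrame, rois: Sequence[str], normalize_wbv: bool = False
) -> pd.DataFrame:
    """Long-format per-subject trajectories for external plotting."""
    frames = []
    for roi in rois:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "study": cohort["study"],
                    "group": cohort["group"],
                    "cap": cohort["cap"],
                    "roi": roi,
                    "response": make_response(cohort, roi, normalize_wbv),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_fit(
    cohort: pd.DataFrame, out_dir, config: RunConfig = RunConfig()
) -> dict:
    """Run the full analysis and write all artifacts to ``out_dir``.

    Writes per-ROI fit JSONs, the ranked changepoint table, trend-line and
    spaghetti CSVs, the exclusion report, and the resolved configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = analyze_cohort(cohort, config)

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
    (out / "exclusion_report.json").write_text(
        json.dumps(res["exclusion_report"], indent=2)
    )
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    for roi, a in res["analyses"].items():
        (fits_dir / f"{roi}.json").write_text(json.dumps(a.fit.to_dict(), indent=2))
    res["table"].to_csv(out / "changepoint_table.csv", index=False)
    trend_lines(res["analyses"]).to_csv(out / "trend_lines.csv", index=False)
    rois = list(res["analyses"])
    spaghetti_data(res["cohort"], rois, config.normalize_wbv).to_csv(
        out / "spaghetti.csv", index=False
    )
    return res


VARIANT_SCHEMES = ("multiplier", "age_identity", "exclude")


def compare_variants(
    cohort: pd.DataFrame,
    config: RunConfig = RunConfig(),
    schemes: Sequence[str] = VARIANT_SCHEMES,
) -> dict:
    """Re-run the analysis across control-CAP schemes × {raw, normalized}.

    Returns a wide per-ROI table of changepoint estimates and preference
    flags for each of the six variants, plus the Spearman rank correlation
    of the changepoint orderings between every pair of variants — the
    robustness check that the ordering of regional changepoints does not
    hinge on how controls are assigned a CAP.
    """
    variants = {}
    for scheme in schemes:
        for normalize in (False, True):
            name = f"{scheme}_{'norm' if normalize else 'raw'}"
            cfg = dataclasses.replace(
                config, cap=config.cap.with_scheme(scheme), normalize_wbv=normalize
            )
            res = analyze_cohort(cohort, cfg)
            variants[name] = res

    rois = list(next(iter(variants.values()))["analyses"])
    table = pd.DataFrame({"roi": rois})
    for name, res in variants.items():
        table[f"tau_{name}"] = [res["analyses"][r].result.tau_hat for r in rois]
        table[f"preferred_{name}"] = [
            res["analyses"][r].result.sigmoid_preferred for r in rois
        ]

    names = list(variants)
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                r = spearmanr(table[f"tau_{a}"], table[f"tau_{b}"]).statistic
                rho.loc[a, b] = rho.loc[b, a] = r
    return {"table": table, "rank_correlations": rho, "variants": variants}
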
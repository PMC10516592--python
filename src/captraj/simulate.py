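"""Synthetic multi-study longitudinal cohorts.

Generates per-scan tables with the statistical structure the trajectory
analysis assumes: three study arms with batch offsets, control and carrier
groups, CAG repeats in the control (15–31) and carrier (38–55) ranges, ages
~18–72 with 1–5 roughly annual visits and attrition, per-subject
intracranial volume, and region volumes that are flat far from onset and
decline sigmoidally in the CAG-Age Product, with basal-ganglia regions
given the earliest changepoints and largest drops.  Controls are generated
disease-free (volumes at the flat level); surrogate CAP assignment happens
downstream in :mod:`captraj.cap`, exactly as for real data.

Whole-brain volume follows its own sigmoid decline, so whole-brain
normalized analyses have non-trivial structure: regions atrophying slower
than the whole brain show *rising* normalized trajectories (relative
sparing).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort import BASAL_GANGLIA_ROIS
from .trajectory import SigmoidParams, left_flat_sigmoid


@dataclass(frozen=True)
class LinearTruth:
    """Straight-line true trajectory (for null calibration studies)."""

    v0: float
    slope: float  # response units per CAP unit

    def curve(self, cap):
        return self.v0 + self.slope * np.asarray(cap, dtype=float)


Truth = Union[SigmoidParams, LinearTruth]


def _truth_curve(truth: Truth, cap):
    if isinstance(truth, LinearTruth):
        return truth.curve(cap)
    return left_flat_sigmoid(cap, truth)


def _truth_level(truth: Truth) -> float:
    return truth.v0


@dataclass(frozen=True)
class CohortScenario:
    """Generative parameters for a synthetic multi-study cohort.

    Study/group offsets are expressed as fractions of each region's flat
    level, so one scenario covers regions whose volumes span two orders of
    magnitude.  ``icv_coupling`` is the fraction of a region's flat level
    gained per relative unit of head size (bigger heads, bigger
    structures).  Noise is Gaussian, homoscedastic per region, with SD
    ``noise_sd_fraction × v0`` (Student-t with 4 df when
    ``heavy_tails=True``).
    """

    n_controls: int = 100
    n_carriers: int = 300
    study_weights: dict = field(
        default_factory=lambda: {"A": 0.12, "B": 0.35, "C": 0.53}
    )
    cag_range_control: tuple = (15, 31)
    cag_mean_control: float = 20.4
    cag_sd_control: float = 3.5
    cag_range_carrier: tuple = (38, 55)
    cag_mean_carrier: float = 42.7
    cag_sd_carrier: float = 2.4
    age_range: tuple = (18.0, 72.0)
    max_visits: int = 5
    visit_gap_years: float = 1.0
    visit_gap_sd: float = 0.15
    retention: float = 0.85
    icv_mean: float = 1.5e6
    icv_sd: float = 1.2e5
    icv_coupling: float = 0.4
    wbv_truth: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(v0=1.12e6, delta=0.09e6, tau=370.0, scale=80.0)
    )
    study_batch_frac: dict = field(
        default_factory=lambda: {"A": 0.0, "B": -0.02, "C": 0.015}
    )
    group_frac: dict = field(
        default_factory=lambda: {"control": 0.0, "premanifest": 0.0, "manifest": -0.01}
    )
    roi_truths: dict = field(default_factory=dict)
    noise_sd_fraction: float = 0.03
    artefact_rate: float = 0.02
    manifest_cap_threshold: float = 400.0
    threshold_l: float = 33.66
    heavy_tails: bool = False
    clinical: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.study_weights.values()) - 1.0) > 1e-9:
            raise ValueError("study weights must sum to 1")
        for lo, hi in (self.cag_range_control, self.cag_range_carrier, self.age_range):
            if not lo < hi:
                raise ValueError(f"range ({lo}, {hi}) not ordered")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if not 0 <= self.artefact_rate < 1:
            raise ValueError("artefact_rate must be in [0, 1)")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if not self.roi_truths:
            raise ValueError("scenario needs at least one ROI truth")

    def replace(self, **kw) -> "CohortScenario":
        return dataclasses.replace(self, **kw)

    def to_json(self, path=None) -> str:
        def enc(o):
            if isinstance(o, (SigmoidParams, LinearTruth)):
                d = dataclasses.asdict(o)
                d["_type"] = type(o).__name__
                return d
            raise TypeError(o)

        text = json.dumps(dataclasses.asdict(self), default=enc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


#: Synthetic per-region trajectory truths (flat level mm³, total drop,
#: changepoint in CAP units, transition width).  These are package
#: fixtures chosen to reproduce the qualitative structure of HD atrophy —
#: basal-ganglia regions earliest and steepest, cortex and white matter
#: later and milder, cerebellum/hippocampus nearly spared — not estimates
#: from any real cohort.
DEFAULT_ROI_TRUTHS: dict = {
    "putamen": SigmoidParams(8200.0, 0.45 * 8200, 250.0, 60.0),
    "caudate": SigmoidParams(7400.0, 0.40 * 7400, 255.0, 60.0),
    "globus_pallidus": SigmoidParams(2600.0, 0.35 * 2600, 300.0, 65.0),
    "nucleus_accumbens": SigmoidParams(750.0, 0.35 * 750, 305.0, 65.0),
    "substantia_nigra": SigmoidParams(600.0, 0.28 * 600, 320.0, 70.0),
    "thalamus": SigmoidParams(12500.0, 0.20 * 12500, 360.0, 80.0),
    "prcwm": SigmoidParams(19000.0, 0.16 * 19000, 340.0, 75.0),
    "prcg": SigmoidParams(15800.0, 0.10 * 15800, 420.0, 90.0),
    "sfwm": SigmoidParams(26000.0, 0.12 * 26000, 400.0, 85.0),
    "sfg": SigmoidParams(34000.0, 0.08 * 34000, 430.0, 90.0),
    "spwm": SigmoidParams(14000.0, 0.10 * 14000, 410.0, 85.0),
    "spg": SigmoidParams(15500.0, 0.08 * 15500, 440.0, 90.0),
    "sowm": SigmoidParams(7500.0, 0.08 * 7500, 430.0, 90.0),
    "sog": SigmoidParams(9500.0, 0.06 * 9500, 450.0, 95.0),
    "stwm": SigmoidParams(16000.0, 0.10 * 16000, 420.0, 85.0),
    "stg": SigmoidParams(21000.0, 0.08 * 21000, 440.0, 90.0),
    "hippocampus": SigmoidParams(6800.0, 0.10 * 6800, 400.0, 90.0),
    "cerebellum": SigmoidParams(140000.0, 0.04 * 140000, 460.0, 100.0),
}


def default_hd_scenario(**overrides) -> CohortScenario:
    """Default scenario: full region set with basal-ganglia-first truths."""
    kw = dict(roi_truths=dict(DEFAULT_ROI_TRUTHS))
    kw.update(overrides)
    return CohortScenario(**kw)


def _draw_cag(rng, mean, sd, lo, hi, size):
    cag = np.rint(rng.normal(mean, sd, size=size))
    return np.clip(cag, lo, hi).astype(int)


def generate_cohort(scenario: CohortScenario, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one synthetic cohort table, reproducible from the seed.

    Carrier volumes follow each region's true trajectory at the subject's
    true CAP, ``age × (CAG − L)``; controls are generated at the flat level
    (disease-free).  The returned frame has no ``cap`` column — surrogate
    CAP assignment is the analysis pipeline's job.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    studies = sorted(scenario.study_weights)
    weights = np.array([scenario.study_weights[s] for s in studies])

    rows = []
    n_total = scenario.n_controls + scenario.n_carriers
    for i in range(n_total):
        carrier = i >= scenario.n_controls
        sid = f"S{i:04d}"
        study = studies[rng.choice(len(studies), p=weights)]
        if carrier:
            cag = _draw_cag(
                rng,
                scenario.cag_mean_carrier,
                scenario.cag_sd_carrier,
                *scenario.cag_range_carrier,
                size=None,
            )
        else:
            cag = _draw_cag(
                rng,
                scenario.cag_mean_control,
                scenario.cag_sd_control,
                *scenario.cag_range_control,
                size=None,
            )
        age0 = rng.uniform(*scenario.age_range)
        icv = rng.normal(scenario.icv_mean, scenario.icv_sd)

        if carrier:
            cap0 = age0 * (cag - scenario.threshold_l)
            group = (
                "manifest" if cap0 > scenario.manifest_cap_threshold else "premanifest"
            )
        else:
            group = "control"

        n_planned = int(rng.integers(1, scenario.max_visits + 1))
        age = age0
        for visit in range(n_planned):
            if visit > 0:
                if rng.random() > scenario.retention:
                    break
                age = age + max(
                    0.1, rng.normal(scenario.visit_gap_years, scenario.visit_gap_sd)
                )
            rows.append((sid, study, group, visit, age, int(cag), icv, carrier))

    df = pd.DataFrame(
        rows,
        columns=["subject_id", "study", "group", "visit_index", "age", "cag", "icv", "_carrier"],
    )
    carrier_mask = df.pop("_carrier").to_numpy()
    # disease position used for volume generation: true CAP for carriers,
    # deep in the flat limb for controls
    disease_cap = np.where(
        carrier_mask,
        df["age"].to_numpy() * (df["cag"].to_numpy() - scenario.threshold_l),
        0.0,
    )

    n = len(df)
    icv_rel = (df["icv"].to_numpy() - scenario.icv_mean) / scenario.icv_mean
    study_frac = df["study"].map(scenario.study_batch_frac).to_numpy(float)
    group_frac = df["group"].map(scenario.group_frac).to_numpy(float)

    def noise(sd, size):
        if scenario.heavy_tails:
            return rng.standard_t(4, size=size) * sd / np.sqrt(2.0)  # t4 var = 2
        return rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)

    def synthesize(truth: Truth) -> np.ndarray:
        v0 = _truth_level(truth)
        vals = (
            _truth_curve(truth, disease_cap)
            + v0 * study_frac
            + v0 * group_frac
            + scenario.icv_coupling * v0 * icv_rel
            + noise(scenario.noise_sd_fraction * v0, n)
        )
        return vals

    df["whole_brain"] = synthesize(scenario.wbv_truth)
    for roi in sorted(scenario.roi_truths):
        df[roi] = synthesize(scenario.roi_truths[roi])

    if scenario.clinical:
        cap_c = disease_cap
        df["tms"] = np.maximum(0.0, 0.06 * (cap_c - 350.0)) + np.abs(noise(2.0, n))
        df["sdmt"] = np.maximum(10.0, 55.0 - 0.04 * np.maximum(cap_c - 300.0, 0.0)) + noise(4.0, n)
        df["tfc"] = np.clip(13.0 - 0.02 * np.maximum(cap_c - 400.0, 0.0) + noise(0.3, n), 0, 13)
        df["bdi"] = np.abs(noise(5.0, n))

    df["qc_pass"] = rng.random(n) >= scenario.artefact_rate
    return df


def _decode_truth(obj) -> Truth:
    if isinstance(obj, (SigmoidParams, LinearTruth)):
        return obj
    d = dict(obj)
    kind = d.pop("_type", None)
    if kind == "LinearTruth" or (kind is None and "slope" in d):
        return LinearTruth(**d)
    return SigmoidParams(**d)


def scenario_from_dict(data: dict) -> CohortScenario:
    """Build a scenario from a plain mapping (parsed YAML/JSON)."""
    d = dict(data)
    for key in ("cag_range_control", "cag_range_carrier", "age_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "wbv_truth" in d:
        d["wbv_truth"] = _decode_truth(d["wbv_truth"])
    if "roi_truths" in d:
        d["roi_truths"] = {k: _decode_truth(v) for k, v in d["roi_truths"].items()}
    return CohortScenario(**d)


def scenario_from_yaml(path) -> CohortScenario:
    """Load a scenario from a structured key-value (YAML or JSON) file."""
    import yaml

    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def linear_truth_scenario(
    n_carriers: int = 100,
    v0: float = 8000.0,
    slope: float = -1.5,
    noise_sd_fraction: float = 0.03,
    **overrides,
) -> CohortScenario:
    """Carriers-only scenario whose single region declines exactly linearly.

    Used for null-calibration studies of the sigmoid-vs-linear test: with
    no controls and a straight-line truth, the linear model is correctly
    specified.
    """
    kw = dict(
        n_controls=0,
        n_carriers=n_carriers,
        roi_truths={"roi_linear": LinearTruth(v0=v0, slope=slope)},
        noise_sd_fraction=noise_sd_fraction,
        artefact_rate=0.0,
        group_frac={"control": 0.0, "premanifest": 0.0, "manifest": 0.0},
        clinical=False,
    )
    kw.update(overrides)
    return CohortScenario(**kw)
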
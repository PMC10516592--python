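"""CAG-Age Product (CAP) scores.

The CAP score, ``Age × (CAG − L)``, places carriers of the *HTT* CAG
expansion on a single disease-burden axis that combines repeat length and
time of exposure; ``L`` approximates the pathogenic repeat threshold.
Controls have no meaningful CAP, so analyses that pool them with carriers
assign a surrogate: either a fixed multiple of age (spreading controls over
the low-CAP range) or simply CAP = age.  Because controls stand in for
far-from-onset carriers, only controls below an age ceiling (default 40
years) are admitted when a surrogate scheme is active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum repeat length treated as an expansion; shorter repeats must be
#: routed through the control scheme.
CAG_EXPANSION_MIN = 36

CONTROL_SCHEMES = ("multiplier", "age_identity", "exclude")


@dataclass(frozen=True)
class CapConfig:
    """How CAP scores are computed and how controls are handled.

    Parameters
    ----------
    threshold_l
        Repeat-length constant ``L`` in ``CAP = age × (CAG − L)``.
    control_scheme
        ``"multiplier"`` assigns controls ``age × control_multiplier``;
        ``"age_identity"`` assigns ``CAP = age``; ``"exclude"`` drops
        controls entirely (carriers-only analyses).
    control_multiplier
        Surrogate multiplier for the ``"multiplier"`` scheme.  The default
        5.6 puts a cohort of mean age ~45 at a mean surrogate CAP of ~253,
        i.e. in the flat, far-from-onset part of the trajectory.
    control_age_cap
        Controls at or above this age are dropped at assignment time;
        ``None`` disables the filter.
    """

    threshold_l: float = 33.66
    control_scheme: str = "multiplier"
    control_multiplier: float = 5.6
    control_age_cap: Optional[float] = 40.0

    def __post_init__(self) -> None:
        if not self.threshold_l > 0:
            raise ValueError(f"threshold_l must be positive, got {self.threshold_l}")
        if self.control_scheme not in CONTROL_SCHEMES:
            raise ValueError(
                f"control_scheme must be one of {CONTROL_SCHEMES}, got "
                f"{self.control_scheme!r}"
            )
        if self.control_scheme == "multiplier" and not self.control_multiplier > 0:
            raise ValueError(
                f"control_multiplier must be positive, got {self.control_multiplier}"
            )

    def with_scheme(self, scheme: str) -> "CapConfig":
        """Return a copy using a different control scheme."""
        return replace(self, control_scheme=scheme)


def cap_for_carrier(age, cag, config: CapConfig = CapConfig()):
    """CAP score for expansion carriers: ``age × (cag − L)``.

    Accepts scalars or arrays.  Strictly increasing in both arguments for
    ``cag > L``.
    """
    age = np.asarray(age, dtype=float)
    cag = np.asarray(cag, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if np.any(cag < CAG_EXPANSION_MIN):
        raise ValueError(
            f"cag below the expansion threshold ({CAG_EXPANSION_MIN}); "
            "route non-carriers through cap_for_control"
        )
    out = age * (cag - config.threshold_l)
    return float(out) if out.ndim == 0 else out


def cap_for_control(age, config: CapConfig = CapConfig()):
    """Surrogate CAP score for a control subject under ``config``'s scheme."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if config.control_scheme == "age_identity":
        out = age.copy()
    elif config.control_scheme == "multiplier":
        out = age * config.control_multiplier
    else:
        raise ValueError(
            "control_scheme='exclude' assigns no control CAP; drop controls instead"
        )
    return float(out) if out.ndim == 0 else out


def assign_cap(cohort: pd.DataFrame, config: CapConfig = CapConfig()) -> pd.DataFrame:
    """Fill the ``cap`` column of a cohort table.

    Carriers (group ``premanifest``/``manifest``) get ``age × (CAG − L)``
    and must have a CAG value; controls are handled per
    ``config.control_scheme`` and, when ``config.control_age_cap`` is set,
    controls at or above that age are dropped.  Returns a new frame; the
    input is not modified.  The operation is idempotent and row-order
    independent.
    """
    out = cohort.copy()
    is_control = out["group"].eq("control").to_numpy()
    carriers = ~is_control

    missing_cag = carriers & (
        out["cag"].isna().to_numpy() if "cag" in out.columns else np.full(len(out), True)
    )
    if missing_cag.any():
        ids = sorted(out.loc[missing_cag, "subject_id"].unique().tolist())
        raise ValueError(f"carriers with missing CAG repeat length: {ids}")

    n_before = len(out)
    if config.control_scheme == "exclude":
        out = out.loc[carriers].copy()
    elif config.control_age_cap is not None:
        drop = is_control & (out["age"].to_numpy() >= config.control_age_cap)
        out = out.loc[~drop].copy()

    is_control = out["group"].eq("control").to_numpy()
    cap = np.empty(len(out), dtype=float)
    if (~is_control).any():
        cap[~is_control] = cap_for_carrier(
            out.loc[~is_control, "age"].to_numpy(),
            out.loc[~is_control, "cag"].to_numpy(),
            config,
        )
    if is_control.any():
        cap[is_control] = cap_for_control(out.loc[is_control, "age"].to_numpy(), config)
    out["cap"] = cap
    logger.info(
        "assign_cap: %d records in, %d retained (%d dropped by control filter)",
        n_before,
        len(out),
        n_before - len(out),
    )
    return out
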
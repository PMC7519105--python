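"""Friction-coefficient analysis of force-sensor traces.

Per time point the friction force is F_f = sqrt(Fx^2 + Fy^2) and the
friction coefficient mu = F_f / Fz; a trial's coefficient is the mean of
mu(t) over samples with sufficient normal load, and per-sample means pool
all trials of all participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import ForceTrace

__all__ = ["FrictionSummary", "trial_friction", "sample_friction_means"]


@dataclass(frozen=True)
class FrictionSummary:
    """Per-sample mean friction coefficients with contributing counts."""

    means: pd.Series  # indexed by sample id
    counts: pd.Series
    trials: pd.DataFrame  # the per-trial records the means were built from


def trial_friction(trace: ForceTrace, fz_floor: float = 0.1, how: str = "mean_of_ratios") -> float:
    """Friction coefficient of one trial.

    Time points with Fz below ``fz_floor`` (N) are discarded to avoid
    blow-ups near lift-off.  ``how`` selects the pointwise mean of
    F_f/Fz (default) or the ratio of mean forces ("ratio_of_means") as a
    sensitivity check.
    """
    if len(trace.time) == 0:
        raise ValueError("empty force trace")
    keep = trace.fz >= fz_floor
    if not keep.any():
        raise ValueError(f"no samples with Fz >= {fz_floor} N")
    ff = np.hypot(trace.fx[keep], trace.fy[keep])
    fz = trace.fz[keep]
    if how == "mean_of_ratios":
        return float(np.mean(ff / fz))
    if how == "ratio_of_means":
        return float(np.mean(ff) / np.mean(fz))
    raise ValueError(f"unknown averaging mode {how!r}")


def sample_friction_means(records: pd.DataFrame, sample_ids: list[str] | None = None) -> FrictionSummary:
    """Arithmetic per-sample mean of mu over all participants and trials.

    ``records`` needs columns ``sample`` and ``mu`` (participant/trial
    columns are carried through untouched).  If ``sample_ids`` is given,
    every listed sample must be present.
    """
    if "sample" not in records or "mu" not in records:
        raise ValueError("records must have 'sample' and 'mu' columns")
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(records["sample"]))
        if missing:
            raise ValueError(f"no friction records for samples: {missing}")
    grouped = records.groupby("sample")["mu"]
    return FrictionSummary(
        means=grouped.mean(), counts=grouped.count(), trials=records.copy()
    )
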
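"""Psychometric curves, Weibull fits, JNDs and agreement rates.

The stimulus intensity of a 2AFC triplet is the absolute difference of
the two alternatives' dissimilarities to the reference (metric-based), or
the analogous quantity built from per-trial friction coefficients.  The
proportion of decisions matching the prediction, binned over sorted
stimulus intensities, is fitted with the Weibull sigmoid

    P(S) = 1 - 0.5 * exp(-(k*S)^d)

which rises from chance (0.5 at S = 0) to 1.  The just noticeable
difference is the intensity where P crosses a criterion level (0.75 by
default), available in closed form as (-ln(2*(1-level)))^(1/d) / k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observer import DecisionSet, TripletDecision

__all__ = [
    "PsychometricCurve",
    "WeibullFit",
    "AgreementReport",
    "stimulus_metric",
    "stimulus_friction",
    "expected_side",
    "decision_stimuli",
    "friction_stimuli",
    "bin_proportions",
    "weibull",
    "fit_weibull",
    "jnd",
    "agreement_rates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsychometricCurve:
    """Equal-count-binned proportion of expected decisions vs intensity."""

    intensity: np.ndarray  # per-bin mean stimulus intensity
    proportion: np.ndarray  # per-bin fraction of expected decisions
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.intensity) == len(self.proportion) == len(self.counts)):
            raise ValueError("bin arrays differ in length")


@dataclass(frozen=True)
class WeibullFit:
    """Weibull sigmoid parameters: slope k (1/stimulus), shape d."""

    k: float
    d: float
    r: float  # Pearson correlation of fitted vs observed proportions

    def __post_init__(self) -> None:
        if self.k <= 0 or self.d <= 0:
            raise ValueError("Weibull parameters k and d must be positive")


@dataclass(frozen=True)
class AgreementReport:
    """Rates of decisions agreeing with the sample structure (per condition)."""

    table: pd.DataFrame  # columns: condition, n, n_agree, rate_pct, p_value


def stimulus_metric(triplet: TripletDecision, D: pd.DataFrame) -> float:
    """Metric-based stimulus intensity |D(left,ref) - D(right,ref)|."""
    for sid in (triplet.ref_id, triplet.left_id, triplet.right_id):
        if sid not in D.index:
            raise KeyError(f"sample {sid!r} missing from the dissimilarity table")
    return float(
        abs(D.loc[triplet.left_id, triplet.ref_id] - D.loc[triplet.right_id, triplet.ref_id])
    )


def stimulus_friction(mu_left: float, mu_right: float, mu_ref: float) -> float:
    """Friction-based stimulus intensity ||mu_l - mu_ref| - |mu_r - mu_ref||."""
    return float(abs(abs(mu_left - mu_ref) - abs(mu_right - mu_ref)))


def expected_side(d_left: float, d_right: float) -> str | None:
    """Predicted choice: the sample closer to the reference; None on a tie."""
    if d_left < d_right:
        return "left"
    if d_right < d_left:
        return "right"
    logger.info("exact tie in predicted dissimilarity; trial excluded from curves")
    return None


def decision_stimuli(
    decisions: DecisionSet, D: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-decision metric-based intensity and matched flag (ties dropped)."""
    S, matched = [], []
    for d in decisions:
        dl = float(D.loc[d.left_id, d.ref_id])
        dr = float(D.loc[d.right_id, d.ref_id])
        side = expected_side(dl, dr)
        if side is None:
            continue
        S.append(abs(dl - dr))
        matched.append(d.choice == side)
    return np.array(S), np.array(matched, dtype=bool)


def friction_stimuli(
    decisions: DecisionSet, friction_records: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-decision friction-based intensity and matched flag.

    ``friction_records`` holds per-trial coefficients with columns
    participant, trial, sample, mu; trial t of participant p corresponds
    to that participant's t-th decision.
    """
    lookup = friction_records.set_index(["participant", "trial", "sample"])["mu"]
    per_participant: dict[int, int] = {}
    S, matched = [], []
    for d in decisions:
        t = per_participant.get(d.participant, 0)
        per_participant[d.participant] = t + 1
        try:
            mu_ref = float(lookup.loc[(d.participant, t, d.ref_id)])
            mu_l = float(lookup.loc[(d.participant, t, d.left_id)])
            mu_r = float(lookup.loc[(d.participant, t, d.right_id)])
        except KeyError as err:
            raise KeyError(
                f"missing friction record for participant {d.participant}, trial {t}"
            ) from err
        dl, dr = abs(mu_l - mu_ref), abs(mu_r - mu_ref)
        side = expected_side(dl, dr)
        if side is None:
            continue
        S.append(abs(dl - dr))
        matched.append(d.choice == side)
    return np.array(S), np.array(matched, dtype=bool)


def bin_proportions(
    S: np.ndarray, matched: np.ndarray, n_bins: int = 10
) -> PsychometricCurve:
    """Equal-count binning of sorted stimulus intensities.

    Bin sizes differ by at most one; each bin reports its mean intensity
    and the fraction of decisions matching the prediction.
    """
    S = np.asarray(S, dtype=float)
    matched = np.asarray(matched, dtype=bool)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if len(S) < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} decisions for {n_bins} bins")
    order = np.argsort(S, kind="stable")
    chunks = np.array_split(order, n_bins)
    intensity = np.array([S[c].mean() for c in chunks])
    proportion = np.array([matched[c].mean() for c in chunks])
    counts = np.array([len(c) for c in chunks])
    return PsychometricCurve(intensity=intensity, proportion=proportion, counts=counts)


def weibull(S: np.ndarray, k: float, d: float) -> np.ndarray:
    """Weibull sigmoid P(S) = 1 - 0.5 exp(-(k S)^d)."""
    return 1.0 - 0.5 * np.exp(-np.power(k * np.asarray(S, dtype=float), d))


def fit_weibull(curve: PsychometricCurve) -> WeibullFit:
    """Nonlinear least-squares fit of the Weibull sigmoid to binned data.

    Falls back to a coarse grid search when the optimizer does not
    converge from the default start.
    """
    if len(curve.intensity) < 3:
        raise ValueError("need at least 3 bins to fit the sigmoid")
    S, P = curve.intensity, curve.proportion

    s_scale = np.median(S[S > 0]) if np.any(S > 0) else 1.0

    def _try_fit(p0):
        try:
            popt, _ = optimize.curve_fit(
                weibull, S, P, p0=p0, bounds=([1e-8, 1e-8], [np.inf, 20.0]), maxfev=20000
            )
            return popt
        except RuntimeError:
            return None

    popt = _try_fit([1.0 / s_scale, 1.5])
    if popt is None:
        # grid-search fallback over (k, d)
        ks = np.geomspace(0.01 / s_scale, 100.0 / s_scale, 60)
        ds = np.geomspace(0.2, 10.0, 40)
        grid = [(k, d) for k in ks for d in ds]
        sse = [np.sum((weibull(S, k, d) - P) ** 2) for k, d in grid]
        k0, d0 = grid[int(np.argmin(sse))]
        popt = _try_fit([k0, d0])
        if popt is None:
            popt = np.array([k0, d0])
    fitted = weibull(S, *popt)
    if np.std(fitted) == 0 or np.std(P) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(fitted, P)[0])
    return WeibullFit(k=float(popt[0]), d=float(popt[1]), r=r)


def jnd(fit: WeibullFit, level: float = 0.75) -> float:
    """Stimulus intensity where the fitted proportion crosses ``level``.

    Closed form: S* = (-ln(2 (1 - level)))^(1/d) / k; at the standard
    2AFC threshold level 0.75 this is (ln 2)^(1/d) / k.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("level must lie strictly between 0.5 and 1")
    return float((-np.log(2.0 * (1.0 - level))) ** (1.0 / fit.d) / fit.k)


def agreement_rates(
    decisions: DecisionSet, sample_labels: dict[str, tuple[str, float]]
) -> AgreementReport:
    """Rates at which choices pick the structurally matching sample.

    Two unbiased conditions are scored:

    * ``same_topography``: left and right share a Hurst exponent and
      exactly one shares the reference's topographic structure — the rate
      of choosing the topography-matched sample;
    * ``same_hurst``: left and right share a topographic structure and
      exactly one shares the reference's Hurst exponent — the rate of
      choosing the Hurst-matched sample.

    Each rate carries an exact two-sided binomial p-value against chance.
    """
    counts = {"same_topography": [0, 0], "same_hurst": [0, 0]}  # [n, n_agree]
    for d in decisions:
        topo_r, h_r = sample_labels[d.ref_id]
        topo_l, h_l = sample_labels[d.left_id]
        topo_g, h_g = sample_labels[d.right_id]

        if h_l == h_g:
            match_l, match_g = topo_l == topo_r, topo_g == topo_r
            if match_l != match_g:
                counts["same_topography"][0] += 1
                chosen_matches = match_l if d.choice == "left" else match_g
                counts["same_topography"][1] += int(chosen_matches)
        if topo_l == topo_g:
            match_l, match_g = h_l == h_r, h_g == h_r
            if match_l != match_g:
                counts["same_hurst"][0] += 1
                chosen_matches = match_l if d.choice == "left" else match_g
                counts["same_hurst"][1] += int(chosen_matches)

    rows = []
    for cond, (n, n_agree) in counts.items():
        if n == 0:
            rows.append(
                {"condition": cond, "n": 0, "n_agree": 0,
                 "rate_pct": np.nan, "p_value": np.nan}
            )
            continue
        p = stats.binomtest(n_agree, n, 0.5, alternative="two-sided").pvalue
        rows.append(
            {
                "condition": cond,
                "n": n,
                "n_agree": n_agree,
                "rate_pct": 100.0 * n_agree / n,
                "p_value": float(p),
            }
        )
    return AgreementReport(table=pd.DataFrame(rows))
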
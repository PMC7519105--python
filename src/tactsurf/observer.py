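"""Synthetic observer: triplet 2AFC decisions and friction trials.

This module generates the study's data shapes without human participants.
Decisions are drawn from a planted dissimilarity structure (the
curvature-plus-topography metric with a known alpha) through a noisy
choice model; friction trials follow a planted linear dependence of the
friction coefficient on rms curvature with participant- and trial-level
scatter.  Every random draw flows from the config seed, so a rerun of the
same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .metric import dissimilarity_table

__all__ = [
    "ObserverConfig",
    "TripletDecision",
    "DecisionSet",
    "ForceTrace",
    "PRESETS",
    "preset_config",
    "enumerate_triplets",
    "planted_dissimilarity",
    "simulate_decision",
    "simulate_experiment",
    "simulate_friction",
    "simulate_sliding_with_friction",
    "simulate_force_trace",
    "friction_line",
    "FRICTION_SLOPE",
    "FRICTION_INTERCEPT",
]

# Planted friction line: population-mean friction coefficient rises from
# 0.35 to 0.45 as rms curvature goes from 1 to 3.5 mm^-1.
FRICTION_SLOPE = (0.45 - 0.35) / (3.5 - 1.0)  # 0.04 per mm^-1
FRICTION_INTERCEPT = 0.35 - FRICTION_SLOPE * 1.0  # 0.31

# (n_participants, triplets_per_participant, alpha_true) per modality.
# alpha values are the topography saliences reported for each modality;
# the decision noise default reproduces a sliding-touch JND near 0.8 mm^-1.
PRESETS = {
    "visual": (15, 50, 2.68),
    "tapping": (10, 28, 1.22),
    "sliding": (13, 28, 0.97),
}


@dataclass(frozen=True)
class ObserverConfig:
    """Configuration of the synthetic observer.

    ``alpha_true`` is the planted topography salience (mm^-1);
    ``noise_scale`` the logistic scale of decision noise on dissimilarity
    differences (mm^-1); ``lapse`` the probability of a uniformly random
    choice.  Friction scatter is an additive per-participant offset plus
    independent per-measurement noise (both in friction-coefficient units).
    """

    alpha_true: float = 0.97
    noise_scale: float = 0.7
    lapse: float = 0.0
    seed: int = 0
    n_participants: int = 13
    triplets_per_participant: int = 28
    modality: str = "sliding"
    link: str = "logistic"  # or "probit"
    friction_participant_sd: float = 0.05
    friction_trial_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if self.link not in ("logistic", "probit"):
            raise ValueError(f"unknown link {self.link!r}")


def preset_config(modality: str, seed: int = 0, **overrides) -> ObserverConfig:
    """Config matching one of the study arms (visual / tapping / sliding)."""
    try:
        n_p, n_t, alpha = PRESETS[modality]
    except KeyError:
        raise ValueError(f"unknown preset {modality!r}; choose from {sorted(PRESETS)}")
    cfg = ObserverConfig(
        alpha_true=alpha,
        seed=seed,
        n_participants=n_p,
        triplets_per_participant=n_t,
        modality=modality,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class TripletDecision:
    """One 2AFC judgement: which of left/right is more similar to ref."""

    ref_id: str
    left_id: str
    right_id: str
    choice: str  # "left" | "right"
    participant: int
    modality: str

    def __post_init__(self) -> None:
        ids = {self.ref_id, self.left_id, self.right_id}
        if len(ids) != 3:
            raise ValueError("ref, left and right ids must be pairwise distinct")
        if self.choice not in ("left", "right"):
            raise ValueError(f"choice must be 'left' or 'right', got {self.choice!r}")


@dataclass(frozen=True)
class DecisionSet:
    """A collection of triplet decisions plus generation provenance."""

    decisions: tuple[TripletDecision, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __iter__(self):
        return iter(self.decisions)

    def __len__(self) -> int:
        return len(self.decisions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "modality": d.modality,
                    "participant": d.participant,
                    "ref": d.ref_id,
                    "left": d.left_id,
                    "right": d.right_id,
                    "choice": d.choice,
                }
                for d in self.decisions
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "DecisionSet":
        decisions = tuple(
            TripletDecision(
                ref_id=str(r.ref),
                left_id=str(r.left),
                right_id=str(r.right),
                choice=str(r.choice),
                participant=int(r.participant),
                modality=str(r.modality),
            )
            for r in frame.itertuples()
        )
        return cls(decisions=decisions, provenance=provenance or {})


@dataclass(frozen=True)
class ForceTrace:
    """Force-sensor time series during one sliding trial (SI units)."""

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.fx) == len(self.fy) == len(self.fz) == n):
            raise ValueError("force channels must share the time axis length")


def enumerate_triplets(sample_ids: list[str]) -> list[tuple[str, frozenset]]:
    """All (reference, unordered pair) triplets over the sample ids.

    For n samples there are n * C(n-1, 2) triplets; with the nine study
    samples that is 252.
    """
    ids = list(sample_ids)
    if len(set(ids)) < 3:
        raise ValueError("need at least 3 distinct sample ids")
    out = []
    for ref in ids:
        others = [s for s in ids if s != ref]
        for a, b in combinations(others, 2):
            out.append((ref, frozenset((a, b))))
    return out


def planted_dissimilarity(cfg: ObserverConfig, summary: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth dissimilarity table D(alpha_true) used by the observer."""
    return dissimilarity_table(summary, alpha=cfg.alpha_true, variant="euclidean")


def _p_left(delta: float, noise_scale: float, link: str) -> float:
    """P(choose left) for dissimilarity difference D_right,ref - D_left,ref."""
    if noise_scale == 0.0:
        return 0.5 if delta == 0.0 else (1.0 if delta > 0 else 0.0)
    z = delta / noise_scale
    return float(expit(z)) if link == "logistic" else float(ndtr(z))


def simulate_decision(
    triplet: tuple[str, str, str],
    D: pd.DataFrame,
    noise_scale: float,
    lapse: float,
    rng: np.random.Generator,
    participant: int = 0,
    modality: str = "sliding",
    link: str = "logistic",
) -> TripletDecision:
    """Simulate one 2AFC decision for (ref, left, right).

    With probability ``lapse`` the choice is uniform; otherwise left is
    chosen with probability link((D_right,ref - D_left,ref)/noise_scale).
    At noise_scale = 0 the choice is the deterministic argmin (ties are a
    fair coin).
    """
    ref, left, right = triplet
    delta = float(D.loc[right, ref] - D.loc[left, ref])
    if rng.uniform() < lapse:
        p_left = 0.5
    else:
        p_left = _p_left(delta, noise_scale, link)
    choice = "left" if rng.uniform() < p_left else "right"
    return TripletDecision(
        ref_id=ref, left_id=left, right_id=right, choice=choice,
        participant=participant, modality=modality,
    )


def _participant_triplets(
    cfg: ObserverConfig, sample_ids: list[str], rng: np.random.Generator
) -> list[list[tuple[str, str, str]]]:
    """Seeded per-participant triplet subsets with randomized left/right order."""
    triplets = enumerate_triplets(sample_ids)
    if cfg.triplets_per_participant > len(triplets):
        raise ValueError(
            f"{cfg.triplets_per_participant} triplets requested per participant "
            f"but only {len(triplets)} exist"
        )
    out = []
    for _ in range(cfg.n_participants):
        idx = rng.choice(len(triplets), size=cfg.triplets_per_participant, replace=False)
        rows = []
        for i in idx:
            ref, pair = triplets[i]
            a, b = sorted(pair)
            if rng.uniform() < 0.5:
                a, b = b, a
            rows.append((ref, a, b))
        out.append(rows)
    return out


def simulate_experiment(cfg: ObserverConfig, summary: pd.DataFrame) -> DecisionSet:
    """Simulate a full experiment from the planted metric.

    Each participant answers a seeded random subset (without replacement)
    of the 252 triplets; choices follow :func:`simulate_decision` on the
    planted dissimilarity table.
    """
    rng = np.random.default_rng(cfg.seed)
    D = planted_dissimilarity(cfg, summary)
    decisions = []
    for p, rows in enumerate(_participant_triplets(cfg, list(summary.index), rng)):
        for trip in rows:
            decisions.append(
                simulate_decision(
                    trip, D, cfg.noise_scale, cfg.lapse, rng,
                    participant=p, modality=cfg.modality, link=cfg.link,
                )
            )
    return DecisionSet(
        decisions=tuple(decisions),
        provenance={"config": cfg, "basis": "metric"},
    )


def friction_line(kappa: np.ndarray | float) -> np.ndarray | float:
    """Planted population-mean friction coefficient at rms curvature kappa."""
    return FRICTION_INTERCEPT + FRICTION_SLOPE * np.asarray(kappa, dtype=float)


def simulate_friction(
    cfg: ObserverConfig,
    summary: pd.DataFrame,
    n_trials_per_participant: int | None = None,
) -> pd.DataFrame:
    """Simulate per-trial friction coefficients for every sample.

    Each participant carries an additive offset (sd
    ``friction_participant_sd``); each measurement adds independent noise
    (sd ``friction_trial_sd``).  Returns a DataFrame with columns
    participant, trial, sample, mu.
    """
    rng = np.random.default_rng(cfg.seed)
    if n_trials_per_participant is None:
        n_trials_per_participant = cfg.triplets_per_participant
    mu0 = friction_line(summary["kappa"].to_numpy())
    rows = []
    for p in range(cfg.n_participants):
        offset = rng.normal(0.0, cfg.friction_participant_sd)
        for t in range(n_trials_per_participant):
            noise = rng.normal(0.0, cfg.friction_trial_sd, size=len(mu0))
            mus = mu0 + offset + noise
            if np.any(mus <= 0):
                raise ValueError("friction parameterization produced mu <= 0")
            for sample, mu in zip(summary.index, mus):
                rows.append({"participant": p, "trial": t, "sample": sample, "mu": float(mu)})
    return pd.DataFrame(rows)


def simulate_sliding_with_friction(
    cfg: ObserverConfig, summary: pd.DataFrame
) -> tuple[DecisionSet, pd.DataFrame]:
    """Sliding-touch experiment where the observer reads curvature through friction.

    Per trial, the three samples' friction coefficients are drawn from the
    planted line with participant offsets and measurement noise.  The
    observer converts friction differences back to perceived curvature
    differences (the planted slope is part of its percept), combines them
    with the topography term alpha_true, and chooses with logistic noise.
    Returns the decisions and the per-trial friction records (columns
    participant, trial, sample, mu) — the same values the observer used,
    mirroring a force sensor that records every trial.
    """
    rng = np.random.default_rng(cfg.seed)
    topo = dict(zip(summary.index, summary["topo_id"]))
    mu0 = dict(zip(summary.index, friction_line(summary["kappa"].to_numpy())))

    decisions = []
    fric_rows = []
    for p, rows in enumerate(_participant_triplets(cfg, list(summary.index), rng)):
        offset = rng.normal(0.0, cfg.friction_participant_sd)
        for t, (ref, left, right) in enumerate(rows):
            trio = (ref, left, right)
            mus = {
                s: mu0[s] + offset + rng.normal(0.0, cfg.friction_trial_sd) for s in trio
            }
            if any(m <= 0 for m in mus.values()):
                raise ValueError("friction parameterization produced mu <= 0")
            for s in trio:
                fric_rows.append(
                    {"participant": p, "trial": t, "sample": s, "mu": mus[s]}
                )

            def d_tilde(s: str) -> float:
                dk = (mus[s] - mus[ref]) / FRICTION_SLOPE
                a = 0.0 if topo[s] == topo[ref] else cfg.alpha_true
                return float(np.hypot(dk, a))

            delta = d_tilde(right) - d_tilde(left)
            if rng.uniform() < cfg.lapse:
                p_left = 0.5
            else:
                p_left = _p_left(delta, cfg.noise_scale, cfg.link)
            choice = "left" if rng.uniform() < p_left else "right"
            decisions.append(
                TripletDecision(
                    ref_id=ref, left_id=left, right_id=right, choice=choice,
                    participant=p, modality=cfg.modality,
                )
            )
    dset = DecisionSet(
        decisions=tuple(decisions),
        provenance={"config": cfg, "basis": "friction"},
    )
    return dset, pd.DataFrame(fric_rows)


def simulate_force_trace(
    mu_true: float,
    fz_profile: np.ndarray | float,
    motion_period: float = 1.5,
    duration: float = 5.0,
    dt: float = 0.01,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ForceTrace:
    """Force trace of a fingertip sliding in circles at constant friction.

    The lateral force opposes the motion, rotating once per
    ``motion_period`` seconds (typical exploration: 1-2 s per circle):
    Fx = mu * Fz * cos(theta), Fy = mu * Fz * sin(theta).  ``noise`` adds
    multiplicative Gaussian noise to the lateral channels.
    """
    t = np.arange(0.0, duration, dt)
    fz = np.broadcast_to(np.asarray(fz_profile, dtype=float), t.shape).copy()
    if np.any(fz <= 0):
        raise ValueError("fz_profile must be positive")
    theta = 2.0 * np.pi * t / motion_period
    fx = mu_true * fz * np.cos(theta)
    fy = mu_true * fz * np.sin(theta)
    if noise > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        fx = fx * (1.0 + noise * rng.standard_normal(t.shape))
        fy = fy * (1.0 + noise * rng.standard_normal(t.shape))
    return ForceTrace(time=t, fx=fx, fy=fy, fz=fz)
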
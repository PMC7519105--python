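"""Ordinal (non-metric) embedding of triplet similarity judgements.

Samples are placed in an n-dimensional perceptual space by maximizing the
likelihood of the observed 2AFC choices.  The choice model is a logistic
(optionally probit) link on the difference of Euclidean distances to the
reference; a weak Gaussian prior on the coordinates pins the overall
scale, and the centroid/rms-norm convention fixes translation and scale
for reporting.  Rotation and reflection remain arbitrary and are handled
separately by Procrustes alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_ndtr, ndtr

from .observer import DecisionSet, TripletDecision

__all__ = [
    "PerceptualSpace",
    "CvReport",
    "BootstrapReport",
    "EmbeddingError",
    "decision_loglik",
    "fit_embedding",
    "crossvalidate_dims",
    "select_dims_one_se",
    "bootstrap_reliability",
    "procrustes_align",
    "topo_distance_ratio",
    "pairwise_distances",
]

_EPS = 1e-12


class EmbeddingError(RuntimeError):
    """Raised when the likelihood optimization fails on every start."""


@dataclass(frozen=True)
class PerceptualSpace:
    """An n-dimensional embedding of the samples.

    ``coordinates`` is a DataFrame (samples x dimensions) with centroid at
    the origin and rms coordinate norm 1.  ``link_scale`` is the noise
    scale to use with these normalized coordinates so that the fitted
    likelihood is reproduced exactly.
    """

    coordinates: pd.DataFrame
    n_dims: int
    log_likelihood: float
    link: str = "logistic"
    link_scale: float = 1.0
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)

    def distances(self) -> pd.DataFrame:
        return pairwise_distances(self.coordinates)


@dataclass(frozen=True)
class CvReport:
    """Held-out scores per candidate dimensionality (k-fold CV)."""

    table: pd.DataFrame  # columns: n_dims, mean_loglik, sd_loglik, mean_frac_correct
    k: int


@dataclass(frozen=True)
class BootstrapReport:
    """Dispersion of pairwise embedding distances under resampling."""

    n_resamples: int
    pair_cov: pd.Series  # CoV per unordered sample pair
    average_cov: float


def pairwise_distances(coords: pd.DataFrame) -> pd.DataFrame:
    x = coords.to_numpy(dtype=float)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


def _link_logp(z: np.ndarray, link: str) -> np.ndarray:
    """log P for standardized distance differences z (P of the made choice)."""
    if link == "logistic":
        return -np.logaddexp(0.0, -z)
    if link == "probit":
        return log_ndtr(z)
    raise ValueError(f"unknown link {link!r}")


def decision_loglik(
    space: PerceptualSpace,
    decision: TripletDecision,
    link_scale: float | None = None,
) -> float:
    """Log-probability of one recorded choice under an embedding.

    P(left) = link((d(right, ref) - d(left, ref)) / link_scale); the
    log-probability of the actually made choice is returned.
    """
    if link_scale is None:
        link_scale = space.link_scale
    c = space.coordinates
    for sid in (decision.ref_id, decision.left_id, decision.right_id):
        if sid not in c.index:
            raise KeyError(f"sample {sid!r} is not embedded")
    xr = c.loc[decision.ref_id].to_numpy()
    dl = float(np.linalg.norm(c.loc[decision.left_id].to_numpy() - xr))
    dr = float(np.linalg.norm(c.loc[decision.right_id].to_numpy() - xr))
    z = (dr - dl) / link_scale
    if decision.choice == "right":
        z = -z
    return float(_link_logp(np.array([z]), space.link)[0])


def _decision_arrays(
    decisions, ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ref, chosen, other) index arrays for the vectorized likelihood."""
    pos = {s: i for i, s in enumerate(ids)}
    ref, cho, oth = [], [], []
    for d in decisions:
        ref.append(pos[d.ref_id])
        if d.choice == "left":
            cho.append(pos[d.left_id])
            oth.append(pos[d.right_id])
        else:
            cho.append(pos[d.right_id])
            oth.append(pos[d.left_id])
    return np.array(ref), np.array(cho), np.array(oth)


def _nll_and_grad(x_flat, m, n, ref, cho, oth, link, prior_weight):
    X = x_flat.reshape(m, n)
    vc = X[cho] - X[ref]
    vo = X[oth] - X[ref]
    dc = np.sqrt((vc**2).sum(1)) + _EPS
    do = np.sqrt((vo**2).sum(1)) + _EPS
    z = do - dc  # unit link scale during fitting; scale is absorbed by coords

    if link == "logistic":
        nll = np.logaddexp(0.0, -z).sum()
        dz = -expit(-z)  # d(-log sigma(z))/dz
    else:  # probit
        nll = -log_ndtr(z).sum()
        dz = -np.exp(stats.norm.logpdf(z) - log_ndtr(z))
    nll += 0.5 * prior_weight * float((X**2).sum())

    g = np.zeros_like(X)
    co = (dz / do)[:, None] * vo
    cc = (-dz / dc)[:, None] * vc
    np.add.at(g, oth, co)
    np.add.at(g, cho, cc)
    np.add.at(g, ref, -(co + cc))
    g += prior_weight * X
    return nll, g.ravel()


def fit_embedding(
    decisions: DecisionSet,
    n_dims: int = 3,
    n_starts: int = 16,
    seed: int = 0,
    link: str = "logistic",
    prior_weight: float = 0.2,
    maxiter: int = 500,
) -> PerceptualSpace:
    """Maximum-likelihood embedding of the samples from triplet decisions.

    Runs ``n_starts`` seeded quasi-Newton (L-BFGS) optimizations from
    random Gaussian starts and keeps the best likelihood (ties broken by
    start index).  The returned coordinates are centered and scaled to
    unit rms norm; ``link_scale`` compensates so the reported
    ``log_likelihood`` is exact for the normalized coordinates.
    """
    ids = sorted({s for d in decisions for s in (d.ref_id, d.left_id, d.right_id)})
    m = len(ids)
    if m < n_dims + 1:
        raise ValueError(f"{m} samples cannot support a {n_dims}-dimensional embedding")
    ref, cho, oth = _decision_arrays(decisions, ids)
    rng = np.random.default_rng(seed)

    best = None
    n_failed = 0
    for _ in range(n_starts):
        x0 = rng.standard_normal(m * n_dims)
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(m, n_dims, ref, cho, oth, link, prior_weight),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise EmbeddingError(
            f"all {n_starts} optimization starts failed ({n_failed} non-finite)"
        )

    X = best.x.reshape(m, n_dims)
    # data log-likelihood at the optimum (prior excluded)
    z = _z_values(X, ref, cho, oth)
    loglik = float(_link_logp(z, link).sum())

    X = X - X.mean(0)
    lam = np.sqrt(np.mean((X**2).sum(1)))
    if lam <= 0:
        lam = 1.0
    Xn = X / lam
    coords = pd.DataFrame(
        Xn, index=ids, columns=[f"dim{i+1}" for i in range(n_dims)]
    )
    return PerceptualSpace(
        coordinates=coords,
        n_dims=n_dims,
        log_likelihood=loglik,
        link=link,
        link_scale=1.0 / lam,
        provenance={
            "n_decisions": len(decisions),
            "n_starts": n_starts,
            "seed": seed,
            "prior_weight": prior_weight,
        },
    )


def _z_values(X, ref, cho, oth):
    dc = np.sqrt(((X[cho] - X[ref]) ** 2).sum(1))
    do = np.sqrt(((X[oth] - X[ref]) ** 2).sum(1))
    return do - dc


def crossvalidate_dims(
    decisions: DecisionSet,
    dims_list=(1, 2, 3, 4, 5),
    k: int = 10,
    seed: int = 0,
    n_starts: int = 4,
    link: str = "logistic",
) -> CvReport:
    """k-fold cross-validation of embedding dimensionality.

    For each candidate dimensionality, embeddings are fitted on each
    training split and scored on the held-out decisions by mean
    log-likelihood per decision (and fraction of choices predicted
    correctly).
    """
    all_d = list(decisions)
    if len(all_d) < k:
        raise ValueError(f"need at least k={k} decisions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_d))
    folds = np.array_split(order, k)

    rows = []
    for n_dims in dims_list:
        scores, fracs = [], []
        for fi, fold in enumerate(folds):
            test_idx = set(fold.tolist())
            train = DecisionSet(
                tuple(d for i, d in enumerate(all_d) if i not in test_idx)
            )
            test = [all_d[i] for i in fold]
            space = fit_embedding(
                train, n_dims=n_dims, n_starts=n_starts,
                seed=int(rng.integers(2**31)), link=link,
            )
            lls, correct = [], []
            for d in test:
                try:
                    ll = decision_loglik(space, d)
                except KeyError:
                    continue  # sample absent from the training split
                lls.append(ll)
                correct.append(ll > np.log(0.5))
            if lls:
                scores.append(float(np.mean(lls)))
                fracs.append(float(np.mean(correct)))
        rows.append(
            {
                "n_dims": n_dims,
                "mean_loglik": float(np.mean(scores)),
                "sd_loglik": float(np.std(scores, ddof=1)),
                "mean_frac_correct": float(np.mean(fracs)),
            }
        )
    return CvReport(table=pd.DataFrame(rows), k=k)


def select_dims_one_se(report: CvReport) -> int:
    """Smallest dimensionality within one standard error of the best score."""
    t = report.table
    best = t["mean_loglik"].idxmax()
    thr = t.loc[best, "mean_loglik"] - t.loc[best, "sd_loglik"] / np.sqrt(report.k)
    ok = t[t["mean_loglik"] >= thr]
    return int(ok["n_dims"].min())


def bootstrap_reliability(
    decisions: DecisionSet,
    B: int = 1000,
    n_dims: int = 3,
    seed: int = 0,
    n_starts: int = 2,
    link: str = "logistic",
) -> BootstrapReport:
    """Coefficient of variation of pairwise distances over bootstrap refits.

    Decisions are resampled with replacement B times; each resample is
    re-embedded and its normalized pairwise distances collected.  The CoV
    (sd/mean) per sample pair and its average quantify how strongly the
    recovered geometry depends on the particular decisions observed.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    all_d = list(decisions)
    ids = sorted({s for d in all_d for s in (d.ref_id, d.left_id, d.right_id)})
    pairs = list(combinations(ids, 2))
    rng = np.random.default_rng(seed)

    dist_rows = []
    for _ in range(B):
        idx = rng.integers(len(all_d), size=len(all_d))
        resampled = DecisionSet(tuple(all_d[i] for i in idx))
        space = fit_embedding(
            resampled, n_dims=n_dims, n_starts=n_starts,
            seed=int(rng.integers(2**31)), link=link,
        )
        # align the coordinate index set: samples can drop out of a resample
        dmat = space.distances()
        dist_rows.append(
            [dmat.loc[a, b] if (a in dmat.index and b in dmat.index) else np.nan
             for a, b in pairs]
        )
    dists = np.array(dist_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(dists, axis=0)
        sd = np.nanstd(dists, axis=0, ddof=1)
    cov = np.where(mean > 0, sd / mean, 0.0)
    pair_cov = pd.Series(cov, index=pd.Index([f"{a}|{b}" for a, b in pairs], name="pair"))
    return BootstrapReport(
        n_resamples=B, pair_cov=pair_cov, average_cov=float(np.mean(cov))
    )


def procrustes_align(
    space: PerceptualSpace, hurst_values: pd.Series | dict
) -> PerceptualSpace:
    """Rotate the embedding so dimension 1 best tracks the Hurst exponents.

    An orthogonal rotation (no scaling) is applied whose first axis
    maximizes the Pearson correlation between the dimension-1 coordinates
    and the per-sample Hurst values, with the sign fixed so H increases
    along +dim1.  Pairwise distances are unchanged.
    """
    coords = space.coordinates
    h = pd.Series(hurst_values).reindex(coords.index).to_numpy(dtype=float)
    if np.any(np.isnan(h)):
        raise KeyError("hurst_values missing for some embedded samples")
    X = coords.to_numpy(dtype=float)
    hc = h - h.mean()
    if np.allclose(hc, 0.0):
        warnings.warn("all Hurst values equal; returning the space unrotated")
        return space

    # direction maximizing corr(X w, h): the least-squares coefficient vector
    w, *_ = np.linalg.lstsq(X - X.mean(0), hc, rcond=None)
    nw = np.linalg.norm(w)
    if nw == 0:
        warnings.warn("Hurst values uncorrelated with the embedding; unrotated")
        return space
    w = w / nw
    # complete w to an orthonormal basis (first column = w)
    Q, _ = np.linalg.qr(np.column_stack([w, np.eye(space.n_dims)]))
    Q = Q[:, : space.n_dims]
    if np.dot(Q[:, 0], w) < 0:
        Q[:, 0] = -Q[:, 0]
    Xr = (X - X.mean(0)) @ Q
    if stats.pearsonr(Xr[:, 0], h)[0] < 0:
        Xr[:, 0] = -Xr[:, 0]
    new_coords = pd.DataFrame(Xr, index=coords.index, columns=coords.columns)
    return PerceptualSpace(
        coordinates=new_coords,
        n_dims=space.n_dims,
        log_likelihood=space.log_likelihood,
        link=space.link,
        link_scale=space.link_scale,
        provenance={**space.provenance, "procrustes": "dim1 aligned to Hurst order"},
    )


def topo_distance_ratio(
    space: PerceptualSpace, topo_labels: dict | pd.Series, dims: tuple[int, ...] = (2, 3)
) -> float:
    """Between- over within-topography mean distance in a coordinate plane.

    ``dims`` are 1-based coordinate indices (default: the plane spanned by
    dimensions 2 and 3, where topography clusters appear).  Returns
    ``inf`` when all within-cluster distances vanish.
    """
    labels = pd.Series(topo_labels).reindex(space.coordinates.index)
    if labels.nunique() < 2:
        raise ValueError("need at least two distinct topography labels")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"labels with fewer than 2 members: {list(small.index)}")
    cols = [space.coordinates.columns[i - 1] for i in dims]
    X = space.coordinates[cols].to_numpy(dtype=float)
    lab = labels.to_numpy()
    within, between = [], []
    for i, j in combinations(range(len(lab)), 2):
        d = float(np.linalg.norm(X[i] - X[j]))
        (within if lab[i] == lab[j] else between).append(d)
    mw = float(np.mean(within))
    mb = float(np.mean(between))
    if mw == 0.0:
        return float("inf")
    return mb / mw
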
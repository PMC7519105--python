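"""End-to-end orchestration: surfaces -> statistics -> synthetic observer
-> embedding -> metric fit -> psychometrics, with all artifacts on disk."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .embedding import (
    bootstrap_reliability,
    crossvalidate_dims,
    fit_embedding,
    pairwise_distances,
    procrustes_align,
    topo_distance_ratio,
)
from .friction import sample_friction_means
from .metric import fit_alpha, pair_vector
from .observer import preset_config, simulate_experiment, simulate_sliding_with_friction
from .psychometrics import (
    agreement_rates,
    bin_proportions,
    decision_stimuli,
    fit_weibull,
    friction_stimuli,
    jnd,
)
from .roughness import estimate_hurst, height_correlation, roughness_summary
from .surface import SpectrumSpec, generate_sample_matrix

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    All per-stage random seeds are derived from ``seed`` through
    ``numpy.random.SeedSequence.spawn``, so one integer pins the whole run.
    """

    seed: int = 0
    out_dir: str = "tactsurf_run"
    # surface generation
    grid_n: int = 1024
    size: float = 50.0
    target_rms: float = 0.4
    hursts: tuple[float, float, float] = (0.4, 0.6, 0.8)
    # observer
    modality: str = "sliding"
    noise_scale: float = 0.7
    alpha_true: float | None = None  # None: use the modality preset value
    # embedding
    n_dims: int = 3
    n_starts: int = 16
    cv_dims: tuple[int, ...] = ()  # empty: skip cross-validation
    bootstrap_B: int = 0  # 0: skip bootstrap
    # psychometrics
    n_bins: int = 10
    schema_version: int = 1
    extras: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("hursts", "cv_dims"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a report bundle under ``config.out_dir``.

    Returns a dictionary of the headline numbers (also written as
    ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (seed_surf, seed_obs, seed_embed, seed_cv, seed_boot) = _spawn_seeds(config.seed, 5)
    report: dict = {"seed": config.seed}

    # --- generate ---------------------------------------------------------
    try:
        spec = SpectrumSpec(grid_n=config.grid_n, size=config.size, target_rms=config.target_rms)
        topo_seeds = tuple(s + seed_surf for s in (0, 1, 2))
        samples = generate_sample_matrix(seeds=topo_seeds, hursts=config.hursts, spec=spec)
        for s in samples:
            tio.write_heightmap_text(s, out / f"surface_{s.sample_id}.txt")
    except Exception as err:
        raise PipelineError(f"[generate] {err}") from err
    logger.info("generated %d surfaces", len(samples))

    # --- stats ------------------------------------------------------------
    try:
        summary = roughness_summary(samples)
        summary.to_csv(out / "summary.csv")
        dists = np.geomspace(2 * spec.pitch, config.size / 2, 40)
        curves = {s.sample_id: height_correlation(s, dists) for s in samples}
        pd.DataFrame(
            {"distance_mm": dists, **{k: c.values for k, c in curves.items()}}
        ).to_csv(out / "correlation_curves.csv", index=False)
        report["hurst_estimates"] = {
            s.sample_id: estimate_hurst(curves[s.sample_id]) for s in samples
        }
        report["kappa"] = summary["kappa"].to_dict()
    except Exception as err:
        raise PipelineError(f"[stats] {err}") from err

    # --- simulate ---------------------------------------------------------
    try:
        cfg = preset_config(config.modality, seed=seed_obs, noise_scale=config.noise_scale)
        if config.alpha_true is not None:
            cfg = preset_config(
                config.modality, seed=seed_obs,
                noise_scale=config.noise_scale, alpha_true=config.alpha_true,
            )
        if config.modality == "sliding":
            decisions, fric_records = simulate_sliding_with_friction(cfg, summary)
            tio.write_friction(fric_records, out / "friction.csv")
        else:
            decisions = simulate_experiment(cfg, summary)
            fric_records = None
        tio.write_decisions(decisions, out / "decisions.csv")
        report["n_decisions"] = len(decisions)
        report["alpha_true"] = cfg.alpha_true
    except Exception as err:
        raise PipelineError(f"[simulate] {err}") from err

    # --- friction ---------------------------------------------------------
    if fric_records is not None:
        try:
            fsum = sample_friction_means(fric_records, sample_ids=list(summary.index))
            fsum.means.rename("mu_mean").to_csv(out / "mu.csv")
            report["friction_means"] = fsum.means.to_dict()
        except Exception as err:
            raise PipelineError(f"[friction] {err}") from err

    # --- embed ------------------------------------------------------------
    try:
        space = fit_embedding(
            decisions, n_dims=config.n_dims, n_starts=config.n_starts, seed=seed_embed
        )
        space = procrustes_align(space, summary["hurst"])
        tio.write_space(space, out / "space.json")
        report["embedding_loglik"] = space.log_likelihood
        if config.n_dims >= 3:
            report["topo_distance_ratio"] = topo_distance_ratio(
                space, summary["topo_id"], dims=(2, 3)
            )
        if config.cv_dims:
            cv = crossvalidate_dims(decisions, dims_list=config.cv_dims, seed=seed_cv)
            cv.table.to_csv(out / "cv_report.csv", index=False)
            report["cv"] = cv.table.to_dict(orient="records")
        if config.bootstrap_B:
            boot = bootstrap_reliability(
                decisions, B=config.bootstrap_B, n_dims=config.n_dims, seed=seed_boot
            )
            boot.pair_cov.to_csv(out / "bootstrap_cov.csv")
            report["bootstrap_average_cov"] = boot.average_cov
    except Exception as err:
        raise PipelineError(f"[embed] {err}") from err

    # --- fit-metric -------------------------------------------------------
    try:
        _, embed_d = pair_vector(space.distances())
        mfit = fit_alpha(
            embed_d,
            summary["kappa"].to_numpy(),
            summary["topo_id"].to_numpy(),
        )
        tio.write_metric_fit(mfit, out / "metricfit.json")
        report["alpha_fit"] = mfit.alpha
        report["alpha_rho"] = mfit.pearson_rho
    except Exception as err:
        raise PipelineError(f"[fit-metric] {err}") from err

    # --- psychometric -----------------------------------------------------
    try:
        from .metric import dissimilarity_table

        D = dissimilarity_table(summary, alpha=mfit.alpha)
        S, matched = decision_stimuli(decisions, D)
        curve = bin_proportions(S, matched, n_bins=config.n_bins)
        wfit = fit_weibull(curve)
        pd.DataFrame(
            {"S": curve.intensity, "P": curve.proportion, "n": curve.counts}
        ).to_csv(out / "psychometric_metric.csv", index=False)
        report["weibull_metric"] = {"k": wfit.k, "d": wfit.d, "R": wfit.r}
        report["jnd_metric"] = jnd(wfit)
        if fric_records is not None:
            Sf, mf = friction_stimuli(decisions, fric_records)
            fcurve = bin_proportions(Sf, mf, n_bins=config.n_bins)
            wf = fit_weibull(fcurve)
            pd.DataFrame(
                {"S": fcurve.intensity, "P": fcurve.proportion, "n": fcurve.counts}
            ).to_csv(out / "psychometric_friction.csv", index=False)
            report["weibull_friction"] = {"k": wf.k, "d": wf.d, "R": wf.r}
            report["jnd_friction"] = jnd(wf)
        agree = agreement_rates(decisions, samples.labels())
        agree.table.to_csv(out / "agreement.csv", index=False)
        report["agreement"] = agree.table.to_dict(orient="records")
    except Exception as err:
        raise PipelineError(f"[psychometric] {err}") from err

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
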
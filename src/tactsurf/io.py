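"""Readers and writers for the pipeline's plain-text artifact formats.

Schemas (v1):

* heightmap text: header comment lines ``# tactsurf-heightmap v1``,
  ``# pitch_mm``, ``# topo_id``, ``# hurst``, ``# phase_seed``, then the
  row-major height matrix in mm (whitespace-separated).
* decisions CSV: modality,participant,ref,left,right,choice
* friction CSV: participant,trial,sample,mu
* force-trace CSV: t,fx,fy,fz
* perceptual space JSON: {"n_dims", "log_likelihood", "link",
  "link_scale", "coordinates": {sample: [..]}}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import PerceptualSpace
from .metric import MetricFit
from .observer import DecisionSet, ForceTrace
from .surface import Surface

__all__ = [
    "write_heightmap_text",
    "read_heightmap_text",
    "write_heightmap_png",
    "export_false_color",
    "write_decisions",
    "read_decisions",
    "write_friction",
    "read_friction",
    "write_force_trace",
    "read_force_trace",
    "write_space",
    "read_space",
    "write_metric_fit",
    "read_metric_fit",
]


def write_heightmap_text(surface: Surface, path: str | Path) -> None:
    path = Path(path)
    seed = surface.provenance.get("phase_seed", "unknown")
    header = (
        "tactsurf-heightmap v1\n"
        f"pitch_mm {surface.pitch!r}\n"
        f"topo_id {surface.topo_id}\n"
        f"hurst {surface.hurst!r}\n"
        f"phase_seed {seed}\n"
        "units mm, row-major"
    )
    np.savetxt(path, surface.heights, header=header, fmt="%.9e")


def read_heightmap_text(path: str | Path) -> Surface:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split(maxsplit=1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
    heights = np.loadtxt(path)
    pitch = float(meta["pitch_mm"])
    label = (meta.get("topo_id", "T?"), float(meta.get("hurst", "nan")))
    prov = {}
    if meta.get("phase_seed", "unknown") != "unknown":
        prov["phase_seed"] = int(meta["phase_seed"])
    return Surface(heights=heights, pitch=pitch, label=label, provenance=prov)


def write_heightmap_png(surface: Surface, path: str | Path) -> None:
    """16-bit grayscale PNG for visual inspection (min->0, max->65535)."""
    import imageio.v3 as iio

    h = surface.heights
    lo, hi = h.min(), h.max()
    scaled = np.zeros_like(h) + 0.5 if hi == lo else (h - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


def export_false_color(surface: Surface, path: str | Path | None = None) -> np.ndarray:
    """False-color rendering: blue valleys to red crests.

    Returns the RGB array (uint8); writes a PNG when ``path`` is given.
    A flat surface maps to the uniform midpoint color.
    """
    import matplotlib

    h = surface.heights
    lo, hi = h.min(), h.max()
    norm = np.full_like(h, 0.5) if hi == lo else (h - lo) / (hi - lo)
    cmap = matplotlib.colormaps["RdBu_r"]  # low -> blue, high -> red
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), rgb)
    return rgb


def write_decisions(decisions: DecisionSet, path: str | Path) -> None:
    decisions.to_frame().to_csv(path, index=False)


def read_decisions(path: str | Path) -> DecisionSet:
    return DecisionSet.from_frame(pd.read_csv(path), provenance={"source": str(path)})


def write_friction(records: pd.DataFrame, path: str | Path) -> None:
    records[["participant", "trial", "sample", "mu"]].to_csv(path, index=False)


def read_friction(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_force_trace(trace: ForceTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"t": trace.time, "fx": trace.fx, "fy": trace.fy, "fz": trace.fz}
    ).to_csv(path, index=False)


def read_force_trace(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    return ForceTrace(
        time=df["t"].to_numpy(),
        fx=df["fx"].to_numpy(),
        fy=df["fy"].to_numpy(),
        fz=df["fz"].to_numpy(),
    )


def write_space(space: PerceptualSpace, path: str | Path) -> None:
    payload = {
        "schema": "tactsurf-space v1",
        "n_dims": space.n_dims,
        "log_likelihood": space.log_likelihood,
        "link": space.link,
        "link_scale": space.link_scale,
        "coordinates": {
            sid: [float(v) for v in row]
            for sid, row in space.coordinates.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_space(path: str | Path) -> PerceptualSpace:
    payload = json.loads(Path(path).read_text())
    coords = pd.DataFrame.from_dict(payload["coordinates"], orient="index")
    coords.columns = [f"dim{i+1}" for i in range(payload["n_dims"])]
    return PerceptualSpace(
        coordinates=coords,
        n_dims=payload["n_dims"],
        log_likelihood=payload["log_likelihood"],
        link=payload["link"],
        link_scale=payload["link_scale"],
        provenance={"source": str(path)},
    )


def write_metric_fit(fit: MetricFit, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "schema": "tactsurf-metricfit v1",
                "alpha": fit.alpha,
                "pearson_rho": fit.pearson_rho,
                "variant": fit.variant,
            },
            indent=2,
        )
    )


def read_metric_fit(path: str | Path) -> MetricFit:
    p = json.loads(Path(path).read_text())
    return MetricFit(alpha=p["alpha"], pearson_rho=p["pearson_rho"], variant=p["variant"])
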
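"""Synthesis of self-affine randomly rough surfaces.

Surfaces are built in Fourier space from an isotropic roughness spectrum
with a plateau at long wavelengths and a power-law decay toward short
wavelengths controlled by the Hurst exponent H.  Randomness enters only
through the phases of the modes; two surfaces generated from the same phase
seed but different H share their topographic structure (locations of hills
and valleys) while differing in fine-scale roughness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "SpectrumSpec",
    "SpectrumTable",
    "PhaseSet",
    "Surface",
    "SampleSet",
    "build_spectrum",
    "sample_phases",
    "synthesize_surface",
    "generate_surface",
    "generate_sample_matrix",
    "DEFAULT_HURSTS",
]

DEFAULT_HURSTS = (0.4, 0.6, 0.8)


class ConfigurationError(ValueError):
    """Raised when a surface specification violates its invariants."""


class DegenerateSurfaceError(ValueError):
    """Raised when a spectrum has no power and cannot be normalized."""


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of the isotropic roughness spectrum.

    Parameters
    ----------
    grid_n : int
        Height points per side (power of two).
    size : float
        Physical side length in mm.
    lambda_long : float
        Longest wavelength in the spectrum (mm); modes with longer
        wavelength carry zero amplitude.
    lambda_roll : float
        Rolloff wavelength separating the constant-amplitude plateau from
        the power-law band (mm).
    lambda_short : float
        Shortest wavelength in the spectrum (mm).
    hurst : float
        Hurst roughness exponent, 0 < H < 1.  Larger H means a faster decay
        of roughness amplitude toward small scales.
    target_rms : float
        rms height after normalization (mm).
    """

    grid_n: int = 1024
    size: float = 50.0
    lambda_long: float = 25.0
    lambda_roll: float = 7.0
    lambda_short: float = 0.5
    hurst: float = 0.6
    target_rms: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.lambda_short < self.lambda_roll < self.lambda_long <= self.size):
            raise ConfigurationError(
                "cutoff wavelengths must satisfy "
                "0 < lambda_short < lambda_roll < lambda_long <= size; got "
                f"{self.lambda_short}, {self.lambda_roll}, {self.lambda_long}, {self.size}"
            )
        if not 0 < self.hurst < 1:
            raise ConfigurationError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.target_rms <= 0:
            raise ConfigurationError("target_rms must be positive")
        n = self.grid_n
        if n < 4 or (n & (n - 1)) != 0:
            raise ConfigurationError(f"grid_n must be a power of two >= 4, got {n}")

    @property
    def pitch(self) -> float:
        """Grid spacing in mm."""
        return self.size / self.grid_n


@dataclass(frozen=True)
class SpectrumTable:
    """Per-mode amplitudes on the discrete Fourier grid.

    ``q`` holds wavevector magnitudes (mm^-1) and ``amplitude`` the height
    amplitude of each mode (mm, arbitrary overall scale -- the synthesized
    surface is rms-normalized afterwards).
    """

    q: np.ndarray
    amplitude: np.ndarray
    spec: SpectrumSpec

    def __post_init__(self) -> None:
        if self.q.shape != self.amplitude.shape:
            raise ValueError("q and amplitude grids must share a shape")


@dataclass(frozen=True)
class PhaseSet:
    """Random per-mode phases with the conjugate symmetry of a real field."""

    seed: int
    phases: np.ndarray

    def __post_init__(self) -> None:
        if self.phases.ndim != 2 or self.phases.shape[0] != self.phases.shape[1]:
            raise ValueError("phases must be a square 2-D grid")


@dataclass(frozen=True)
class Surface:
    """A synthesized heightmap with physical units.

    ``heights`` is a ``grid_n x grid_n`` array in mm with zero mean and rms
    equal to the spectrum's ``target_rms``.  ``label`` records the
    topography id (phase family) and the Hurst exponent.
    """

    heights: np.ndarray
    pitch: float
    label: tuple[str, float]
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def size(self) -> float:
        return self.pitch * self.heights.shape[0]

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.heights**2)))

    @property
    def topo_id(self) -> str:
        return self.label[0]

    @property
    def hurst(self) -> float:
        return self.label[1]

    @property
    def sample_id(self) -> str:
        return f"{self.label[0]}-H{self.label[1]:g}"


@dataclass(frozen=True)
class SampleSet:
    """The 3 x 3 sample matrix: three phase families x three Hurst exponents."""

    surfaces: tuple[Surface, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.surfaces]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate (topography, hurst) labels in sample set")

    def __iter__(self):
        return iter(self.surfaces)

    def __len__(self) -> int:
        return len(self.surfaces)

    def get(self, topo_id: str, hurst: float) -> Surface:
        for s in self.surfaces:
            if s.topo_id == topo_id and np.isclose(s.hurst, hurst):
                return s
        raise KeyError((topo_id, hurst))

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.surfaces]

    def labels(self) -> dict[str, tuple[str, float]]:
        """Map sample id -> (topography id, hurst)."""
        return {s.sample_id: s.label for s in self.surfaces}


def _wavevector_grid(spec: SpectrumSpec) -> np.ndarray:
    f = np.fft.fftfreq(spec.grid_n, d=spec.pitch)
    qx = 2.0 * np.pi * f
    return np.hypot.outer(qx, qx)


def build_spectrum(spec: SpectrumSpec) -> SpectrumTable:
    """Build the per-mode amplitude table for an isotropic spectrum.

    Modes with ``2*pi/lambda_long <= |q| <= 2*pi/lambda_roll`` share a
    constant amplitude (the plateau); in the power-law band
    ``2*pi/lambda_roll < |q| <= 2*pi/lambda_short`` the amplitude decays as
    ``q^(-1-H)`` (isotropic PSD ~ ``q^(-2-2H)``), continuous at the rolloff.
    All other modes, including q = 0, carry zero amplitude.
    """
    q = _wavevector_grid(spec)
    q_long = 2.0 * np.pi / spec.lambda_long
    q_roll = 2.0 * np.pi / spec.lambda_roll
    q_short = 2.0 * np.pi / spec.lambda_short

    amp = np.zeros_like(q)
    plateau = (q >= q_long) & (q <= q_roll)
    powerlaw = (q > q_roll) & (q <= q_short)
    amp[plateau] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        amp[powerlaw] = (q[powerlaw] / q_roll) ** (-1.0 - spec.hurst)
    return SpectrumTable(q=q, amplitude=amp, spec=spec)


def _conjugate_flip(a: np.ndarray) -> np.ndarray:
    """Map index k -> (-k) mod n on both axes."""
    return np.roll(np.flip(a, axis=(0, 1)), shift=(1, 1), axis=(0, 1))


def sample_phases(seed: int, spec: SpectrumSpec) -> PhaseSet:
    """Draw uniform random phases with conjugate (Hermitian) symmetry.

    Independent modes receive i.i.d. phases uniform on [0, 2*pi); the phase
    at -q is set to the negative of the phase at q so the synthesized
    height field is real.  Self-conjugate modes (q = 0 and Nyquist) get a
    phase of 0 or pi.
    """
    n = spec.grid_n
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))

    idx = np.arange(n)
    neg = (-idx) % n
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    nii, njj = neg[ii], neg[jj]
    # keep the lexicographically smaller member of each (k, -k) pair
    keep = (ii < nii) | ((ii == nii) & (jj < njj))
    self_conj = (ii == nii) & (jj == njj)

    phases = np.where(keep, raw, 0.0)
    flipped = _conjugate_flip(phases)
    phases = np.where(keep, phases, (-flipped) % (2.0 * np.pi))
    # self-conjugate modes must satisfy phi = -phi (mod 2*pi)
    phases[self_conj] = np.where(raw[self_conj] < np.pi, 0.0, np.pi)
    return PhaseSet(seed=seed, phases=phases)


def synthesize_surface(
    table: SpectrumTable,
    phases: PhaseSet,
    target_rms: float | None = None,
    label: tuple[str, float] | None = None,
) -> Surface:
    """Superpose the spectral modes with random phases and normalize the rms.

    The height field is the real inverse FFT of ``amplitude * exp(i*phase)``;
    the mean is subtracted and heights are rescaled so the rms equals
    ``target_rms`` (defaulting to the spec's value).
    """
    spec = table.spec
    if phases.phases.shape != table.amplitude.shape:
        raise ValueError("phase grid does not match the spectrum grid")
    if target_rms is None:
        target_rms = spec.target_rms

    z = table.amplitude * np.exp(1j * phases.phases)
    h = np.fft.ifft2(z).real
    h -= h.mean()
    rms = np.sqrt(np.mean(h**2))
    if rms == 0.0:
        raise DegenerateSurfaceError("spectrum carries no power; cannot normalize rms")
    h *= target_rms / rms

    if label is None:
        label = (f"seed{phases.seed}", spec.hurst)
    return Surface(
        heights=h,
        pitch=spec.pitch,
        label=label,
        provenance={
            "phase_seed": phases.seed,
            "rng": "numpy.random.default_rng (PCG64)",
            "hurst": spec.hurst,
            "spec": spec,
        },
    )


def generate_surface(seed: int, spec: SpectrumSpec, label: tuple[str, float] | None = None) -> Surface:
    """Convenience wrapper: spectrum + phases + synthesis in one call."""
    table = build_spectrum(spec)
    phases = sample_phases(seed, spec)
    return synthesize_surface(table, phases, label=label)


def generate_sample_matrix(
    seeds: tuple[int, int, int] = (11, 22, 33),
    hursts: tuple[float, float, float] = DEFAULT_HURSTS,
    spec: SpectrumSpec | None = None,
) -> SampleSet:
    """Generate the 3 x 3 matrix of samples.

    Each of the three seeds defines one topographic family: the same phase
    set is reused for its three Hurst exponents, so the surfaces in one
    family share hill/valley locations.  Every surface is rms-normalized
    individually.
    """
    if len(set(seeds)) != len(seeds):
        raise ConfigurationError(f"seeds must be distinct, got {seeds}")
    if spec is None:
        spec = SpectrumSpec()

    surfaces = []
    for (t_idx, seed), hurst in product(enumerate(seeds, start=1), hursts):
        hspec = SpectrumSpec(
            grid_n=spec.grid_n,
            size=spec.size,
            lambda_long=spec.lambda_long,
            lambda_roll=spec.lambda_roll,
            lambda_short=spec.lambda_short,
            hurst=hurst,
            target_rms=spec.target_rms,
        )
        table = build_spectrum(hspec)
        phases = sample_phases(seed, hspec)
        surfaces.append(synthesize_surface(table, phases, label=(f"T{t_idx}", hurst)))
    return SampleSet(surfaces=tuple(surfaces))
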
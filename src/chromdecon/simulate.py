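"""Synthetic GC/MS chromatogram generator with known ground truth.

Emulates a quadrupole EI full-scan acquisition (default m/z 50-450,
3.6 scans/s) with Gaussian-shaped elution peaks, an optional flat matrix
background plus broad interferent components, and additive noise clamped
at zero. Every generated chromatogram comes with a truth manifest so that
downstream deconvolution can be scored against construction parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chrom_io import Chromatogram, LibrarySpectrum

__all__ = [
    "GroundTruthComponent",
    "SimulationSpec",
    "simulate_chromatogram",
    "spectrum_cosine",
]

DEFAULT_SCAN_RATE = 3.6  # scans per second, quadrupole full scan
DEFAULT_MZ_RANGE = (50, 450)


@dataclass
class GroundTruthComponent:
    """One analyte (or interferent) with a known elution peak.

    The elution profile is a Gaussian ``amount * N(t; retention_time,
    peak_width_sigma)`` (unit area in time), so ``amount`` is the total
    chromatographic area of the component in arbitrary count*minute units.
    """

    spectrum: LibrarySpectrum
    retention_time: float  # minutes
    peak_width_sigma: float  # minutes
    amount: float = 1.0
    saturation_level: float | None = None  # flat-top clipping for overloads

    def __post_init__(self) -> None:
        if self.peak_width_sigma <= 0:
            raise ValueError(f"{self.spectrum.name}: sigma must be > 0")
        if self.amount < 0:
            raise ValueError(f"{self.spectrum.name}: amount must be >= 0")


@dataclass
class SimulationSpec:
    """Full description of one simulated acquisition."""

    run_length: float  # minutes
    components: list = field(default_factory=list)
    scan_rate: float = DEFAULT_SCAN_RATE  # scans/s
    mz_range: tuple = DEFAULT_MZ_RANGE
    baseline_level: float = 0.0
    noise_sd: float = 0.0
    matrix_components: list = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _gaussian_profile(times: np.ndarray, rt: float, sigma: float) -> np.ndarray:
    z = (times - rt) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def simulate_chromatogram(spec: SimulationSpec):
    """Generate a chromatogram and its ground-truth manifest.

    The signal is the sum over components of
    ``amount * Gaussian(t; rt, sigma) (outer) unit-norm spectrum``, plus a
    constant baseline and truncated-Gaussian noise (clamped at zero).
    Deterministic given ``spec.rng_seed``.

    Returns
    -------
    (Chromatogram, dict)
        The chromatogram and a manifest recording, per component, the scan
        span containing 99.99% of its mass and its per-scan TIC contribution.
    """
    n_scans = max(int(round(spec.run_length * 60.0 * spec.scan_rate)), 2)
    scan_times = np.arange(n_scans) / (spec.scan_rate * 60.0)  # minutes
    lo, hi = spec.mz_range
    mz_axis = np.arange(int(lo), int(hi) + 1)
    intensities = np.zeros((n_scans, mz_axis.size))

    manifest = {
        "rng_seed": spec.rng_seed,
        "scan_rate_per_s": spec.scan_rate,
        "baseline_level": spec.baseline_level,
        "noise_sd": spec.noise_sd,
        "components": [],
    }

    for comp in list(spec.components) + list(spec.matrix_components):
        if not (scan_times[0] <= comp.retention_time <= scan_times[-1]):
            raise ValueError(
                f"component {comp.spectrum.name!r}: retention time "
                f"{comp.retention_time} min outside run span "
                f"[{scan_times[0]:.4f}, {scan_times[-1]:.4f}]"
            )
        dense = comp.spectrum.normalize().to_dense(mz_axis)
        dense = dense / dense.sum()  # spectrum as a probability over m/z
        profile = comp.amount * _gaussian_profile(
            scan_times, comp.retention_time, comp.peak_width_sigma
        )
        block = np.outer(profile, dense)
        if comp.saturation_level is not None:
            block = np.minimum(block, comp.saturation_level)
        intensities += block
        span = np.nonzero(profile > 1e-4 * profile.max())[0]
        manifest["components"].append(
            {
                "name": comp.spectrum.name,
                "retention_time_min": comp.retention_time,
                "sigma_min": comp.peak_width_sigma,
                "amount": comp.amount,
                "scan_span": [int(span[0]), int(span[-1])],
                "tic_contribution": block.sum(axis=1).tolist(),
            }
        )

    intensities += spec.baseline_level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        intensities += rng.normal(0.0, spec.noise_sd, size=intensities.shape)
    np.maximum(intensities, 0.0, out=intensities)

    chrom = Chromatogram(
        scan_times,
        mz_axis,
        intensities,
        metadata={"source": "simulated", "rng_seed": str(spec.rng_seed)},
    )
    return chrom, manifest


def spectrum_cosine(a: LibrarySpectrum, b: LibrarySpectrum) -> float:
    """Cosine similarity between two centroided spectra on their union grid."""
    mzs = sorted(a.mz_values() | b.mz_values())
    grid = np.array(mzs, dtype=int)
    va = a.to_dense(grid)
    vb = b.to_dense(grid)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero spectrum")
    return float(np.dot(va, vb) / (na * nb))
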
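"""Pseudo-replicate generation from a single chromatogram.

PARAFAC2-based deconvolution needs several samples with independent
variation (at least five). When only one run is available, a replicate set
is derived from it by scaling all intensities by a multiplier and shifting
retention time by a small sub-scan offset, mimicking the run-to-run
variation of real injections. At 3.6 scans/s one scan is ~0.0046 min, so
typical offsets (|offset| <= 0.003 min) are below one scan spacing and the
shift must be realised by interpolation, not by rolling indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .chrom_io import Chromatogram

__all__ = [
    "ReplicateSpec",
    "ReplicateSet",
    "multiply",
    "shift_rt",
    "denoise",
    "make_replicate_set",
    "MULTIPLIER_RANGE",
    "RT_OFFSET_RANGE",
    "MIN_REPLICATES",
]

# Nominal parameter ranges for drawing replicate specs; multipliers outside
# MULTIPLIER_RANGE are accepted with a warning (documented usage includes
# factors up to ~2).
MULTIPLIER_RANGE = (0.5, 1.5)
RT_OFFSET_RANGE = (-0.003, 0.003)  # minutes
MIN_REPLICATES = 5  # set size required by the downstream factor model

SAVGOL_WINDOW = 5
SAVGOL_ORDER = 2


@dataclass(frozen=True)
class ReplicateSpec:
    """(retention-time offset [min], intensity multiplier) for one member."""

    rt_offset: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError(f"multiplier must be > 0, got {self.multiplier}")
        lo, hi = MULTIPLIER_RANGE
        if not (lo <= self.multiplier <= hi):
            warnings.warn(
                f"multiplier {self.multiplier} outside the nominal "
                f"[{lo}, {hi}] range",
                stacklevel=2,
            )


@dataclass
class ReplicateSet:
    """K co-registered chromatograms: member 0 is the original."""

    members: list
    specs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < MIN_REPLICATES:
            raise ValueError(
                f"a replicate set needs at least {MIN_REPLICATES} members "
                f"(one original plus derived pseudo-replicates); "
                f"got {len(self.members)}"
            )
        ref = self.members[0]
        for k, m in enumerate(self.members[1:], start=1):
            if not np.array_equal(m.mz_axis, ref.mz_axis):
                raise ValueError(f"member {k}: m/z axis differs from member 0")
            if m.n_scans != ref.n_scans:
                raise ValueError(f"member {k}: scan count differs from member 0")

    def __len__(self) -> int:
        return len(self.members)


def multiply(chrom: Chromatogram, factor: float) -> Chromatogram:
    """Scale every intensity by ``factor``; scan times unchanged."""
    if factor <= 0:
        raise ValueError(f"multiplier must be > 0, got {factor}")
    out = chrom.copy()
    out.intensities = out.intensities * factor
    out.metadata["multiplier"] = repr(factor)
    return out


def shift_rt(chrom: Chromatogram, offset: float) -> Chromatogram:
    """Shift the signal in retention time by ``offset`` minutes.

    The shifted signal is resampled back onto the original scan-time grid by
    per-channel linear interpolation, so all members of a replicate set stay
    co-registered. A peak at time t in the input appears at t + offset in
    the output. Out-of-range regions hold the edge scan's values.
    """
    span = chrom.scan_times[-1] - chrom.scan_times[0]
    if abs(offset) >= span:
        raise ValueError(f"|offset| = {abs(offset)} min >= run span {span} min")
    out = chrom.copy()
    if offset != 0.0:
        # value at grid time t comes from the original signal at t - offset
        source_times = chrom.scan_times - offset
        out.intensities = np.column_stack(
            [
                np.interp(source_times, chrom.scan_times, chrom.intensities[:, j])
                for j in range(chrom.n_mz)
            ]
        )
    out.metadata["rt_offset_min"] = repr(offset)
    return out


def denoise(chrom: Chromatogram, window: int = SAVGOL_WINDOW,
            order: int = SAVGOL_ORDER) -> Chromatogram:
    """Savitzky-Golay smoothing per m/z channel, clamped at zero.

    Defaults (window 5 scans, polynomial order 2) preserve polynomials up to
    degree 2 exactly, so baselines and linear ramps pass through unchanged
    while high-frequency noise is attenuated.
    """
    if chrom.n_scans < window:
        raise ValueError(
            f"need at least {window} scans for the denoising window, "
            f"got {chrom.n_scans}"
        )
    out = chrom.copy()
    smoothed = savgol_filter(out.intensities, window, order, axis=0)
    out.intensities = np.maximum(smoothed, 0.0)
    out.metadata["denoise"] = f"savgol(window={window}, order={order})"
    return out


def make_replicate_set(
    chrom: Chromatogram,
    specs=None,
    denoise_flag: bool = False,
    rng_seed: int | None = None,
    n_derived: int = MIN_REPLICATES - 1,
) -> ReplicateSet:
    """Build a replicate set: the original plus >= 4 derived members.

    Member k+1 = shift_rt(multiply(original, m_k), d_k), optionally
    denoised (the original is denoised too in that case, so all members see
    the same filter). Specs may be given explicitly or drawn with
    ``rng_seed``: multiplier ~ U[0.5, 1.5], offset ~ U[-0.003, 0.003] min.
    """
    if specs is None:
        if rng_seed is None:
            raise ValueError(
                f"need at least {MIN_REPLICATES - 1} replicate specs or an "
                f"rng_seed: the factor model requires {MIN_REPLICATES} samples"
            )
        rng = np.random.default_rng(rng_seed)
        specs = [
            ReplicateSpec(
                rt_offset=float(rng.uniform(*RT_OFFSET_RANGE)),
                multiplier=float(rng.uniform(*MULTIPLIER_RANGE)),
            )
            for _ in range(n_derived)
        ]
    specs = list(specs)
    if len(specs) < MIN_REPLICATES - 1:
        raise ValueError(
            f"got {len(specs)} replicate specs; at least "
            f"{MIN_REPLICATES - 1} derived members are required so the set "
            f"reaches the {MIN_REPLICATES}-sample minimum"
        )

    original = denoise(chrom) if denoise_flag else chrom.copy()
    members = [original]
    for spec in specs:
        member = shift_rt(multiply(chrom, spec.multiplier), spec.rt_offset)
        if denoise_flag:
            member = denoise(member)
        members.append(member)
    return ReplicateSet(members=members, specs=specs)
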
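"""Shared fixtures: synthetic spectra, chromatograms, replicate sets."""

import numpy as np
import pytest

from chromdecon.augment import ReplicateSpec, make_replicate_set
from chromdecon.chrom_io import LibrarySpectrum
from chromdecon.intervals import Interval, build_cube
from chromdecon.simulate import (
    GroundTruthComponent,
    SimulationSpec,
    simulate_chromatogram,
)

# EI-like synthetic reference spectra with disjoint m/z support, so cosine
# against truth is a sharp recovery metric
SPEC_A = LibrarySpectrum(
    "analyte-A", [(100, 999), (272, 500), (274, 480), (237, 300),
                  (117, 250), (65, 150)]
)
SPEC_B = LibrarySpectrum(
    "analyte-B", [(285, 999), (287, 760), (125, 640), (109, 500),
                  (79, 300), (63, 220)]
)

MULTIPLIERS = (1.0, 0.5, 1.5, 0.8, 1.2)
OFFSETS = (0.001, -0.002, 0.0015, -0.001)


@pytest.fixture(scope="session")
def spec_a():
    return SPEC_A


@pytest.fixture(scope="session")
def spec_b():
    return SPEC_B


def make_single_analyte(seed=0, noise_sd=0.0, amount=5000.0, rt=0.20):
    spec = SimulationSpec(
        run_length=0.4,
        components=[GroundTruthComponent(SPEC_A, rt, 0.01, amount=amount)],
        noise_sd=noise_sd,
        rng_seed=seed,
    )
    return simulate_chromatogram(spec)


def make_coelution(seed=0, noise_sd=0.0, rt_gap=0.01):
    """Two co-eluting analytes with disjoint spectra."""
    spec = SimulationSpec(
        run_length=0.4,
        components=[
            GroundTruthComponent(SPEC_A, 0.20, 0.01, amount=5000.0),
            GroundTruthComponent(SPEC_B, 0.20 + rt_gap, 0.01, amount=4000.0),
        ],
        noise_sd=noise_sd,
        rng_seed=seed,
    )
    return simulate_chromatogram(spec)


def fixed_specs():
    return [ReplicateSpec(o, m) for o, m in zip(OFFSETS, MULTIPLIERS[1:])]


@pytest.fixture(scope="session")
def single_analyte_cube():
    """Noiseless rank-1 pseudo-replicate cube with known multipliers."""
    chrom, _ = make_single_analyte()
    repset = make_replicate_set(chrom, specs=fixed_specs())
    cube = build_cube(repset, Interval(0.175, 0.24, "single"))
    return cube, MULTIPLIERS


@pytest.fixture(scope="session")
def coelution_cube():
    """Noiseless two-component pseudo-replicate cube (1-sigma apart)."""
    chrom, _ = make_coelution()
    repset = make_replicate_set(chrom, specs=fixed_specs())
    cube = build_cube(repset, Interval(0.175, 0.24, "coelution"))
    return cube, MULTIPLIERS


def generic_cube(r, seed=0, k=5, i=30, j=120, noise_sd=0.0):
    """Cube with independent per-component sample amounts (full-rank C).

    Built directly from the PARAFAC2 parameterization with Gaussian elution
    profiles shifted per component, disjoint block spectra and random
    amounts; this is the generic (non-pseudo-replicate) regime where the
    classic model is identifiable and CORCONDIA is well defined.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, i)
    profiles = np.column_stack(
        [np.exp(-0.5 * ((t - 0.35 - 0.12 * p) / 0.06) ** 2) for p in range(r)]
    )
    spectra = np.zeros((j, r))
    block = j // r
    for p in range(r):
        spectra[p * block:(p + 1) * block, p] = rng.uniform(
            0.2, 1.0, size=block
        )
    amounts = rng.uniform(0.5, 2.0, size=(k, r))
    slabs = []
    for kk in range(k):
        x = profiles @ np.diag(amounts[kk]) @ spectra.T
        if noise_sd:
            x = np.maximum(x + rng.normal(0, noise_sd, x.shape), 0.0)
        slabs.append(x)
    from chromdecon.intervals import IntervalCube

    cube = IntervalCube(
        slabs=slabs,
        interval=Interval(0.0, 1.0, f"generic{r}"),
        member_ids=list(range(k)),
        mz_axis=np.arange(50, 50 + j),
        scan_times=t,
    )
    return cube, profiles, spectra, amounts
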
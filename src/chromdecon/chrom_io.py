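"""Chromatogram and spectral-library I/O.

Reads and writes GC/MS scan chromatograms in the ANDI/AIA netCDF (CDF)
interchange format and in an internal human-inspectable dense CSV dialect,
and parses NIST MSP text libraries of centroided reference spectra.

All retention times are in minutes. Mass spectra live on a unit-spaced
integer m/z grid (quadrupole unit resolution); raw centroid m/z values are
rounded to the nearest integer and collisions summed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import netcdf_file

__all__ = [
    "Chromatogram",
    "LibrarySpectrum",
    "ChromatogramFormatError",
    "read_cdf",
    "write_cdf",
    "read_msp",
    "write_msp",
    "read_dense_csv",
    "write_dense_csv",
]

MAX_RELATIVE_INTENSITY = 999


class ChromatogramFormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class Chromatogram:
    """One GC/MS run as a dense scan-time x m/z intensity matrix.

    Parameters
    ----------
    scan_times
        Scan acquisition times in minutes, strictly increasing, length I.
    mz_axis
        Integer m/z bins on a unit-spaced grid, strictly increasing, length J.
    intensities
        I x J matrix of non-negative ion counts.
    metadata
        Free-form key -> string map (instrument, sample id, provenance).
    """

    scan_times: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.scan_times.ndim != 1 or self.scan_times.size < 2:
            raise ValueError("need at least 2 scans")
        if self.mz_axis.ndim != 1 or self.mz_axis.size < 2:
            raise ValueError("need at least 2 m/z bins")
        if np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan_times must be strictly increasing")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")
        if self.intensities.shape != (self.scan_times.size, self.mz_axis.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"(I={self.scan_times.size}, J={self.mz_axis.size})"
            )
        neg = self.intensities < 0
        if neg.any():
            warnings.warn(
                f"clamped {int(neg.sum())} negative intensity cells to 0",
                stacklevel=2,
            )
            self.intensities = np.where(neg, 0.0, self.intensities)
            self.metadata.setdefault("negative_cells_clamped", str(int(neg.sum())))

    @property
    def n_scans(self) -> int:
        return self.scan_times.size

    @property
    def n_mz(self) -> int:
        return self.mz_axis.size

    def tic(self) -> np.ndarray:
        """Total ion chromatogram: per-scan sum over all m/z bins."""
        return self.intensities.sum(axis=1)

    def copy(self) -> "Chromatogram":
        return Chromatogram(
            self.scan_times.copy(),
            self.mz_axis.copy(),
            self.intensities.copy(),
            dict(self.metadata),
        )


@dataclass
class LibrarySpectrum:
    """Centroided reference mass spectrum.

    ``peaks`` is a list of ``(integer m/z, relative intensity)`` pairs;
    after :meth:`normalize` the base peak carries intensity 999 (the NIST
    relative-abundance convention).
    """

    name: str
    peaks: list
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"spectrum {self.name!r} has no peaks")
        mzs = [p[0] for p in self.peaks]
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"spectrum {self.name!r} has duplicate m/z values")

    def normalize(self) -> "LibrarySpectrum":
        """Rescale so the base peak has intensity 999 (rounded to int)."""
        base = max(i for _, i in self.peaks)
        if base <= 0:
            raise ValueError(f"spectrum {self.name!r} is all zero")
        peaks = [
            (int(mz), int(round(i * MAX_RELATIVE_INTENSITY / base)))
            for mz, i in self.peaks
        ]
        return LibrarySpectrum(self.name, peaks, self.retention_time)

    def to_dense(self, mz_axis: np.ndarray) -> np.ndarray:
        """Project onto a dense integer m/z grid (off-grid peaks dropped)."""
        mz_axis = np.asarray(mz_axis, dtype=int)
        out = np.zeros(mz_axis.size)
        index = {int(m): k for k, m in enumerate(mz_axis)}
        for mz, inten in self.peaks:
            k = index.get(int(mz))
            if k is not None:
                out[k] += inten
        return out

    def mz_values(self) -> set:
        return {int(mz) for mz, _ in self.peaks}


# ---------------------------------------------------------------------------
# ANDI/AIA netCDF
# ---------------------------------------------------------------------------

_ANDI_REQUIRED = (
    "scan_acquisition_time",
    "scan_index",
    "point_count",
    "mass_values",
    "intensity_values",
)


def read_cdf(path) -> Chromatogram:
    """Read an ANDI-MS (AIA) netCDF chromatogram.

    Sparse per-scan centroid lists are binned onto the unit integer m/z
    grid spanning the file's observed (rounded) m/z range; collisions within
    a bin are summed. Scan times are converted from seconds to minutes.
    """
    with netcdf_file(str(path), "r", mmap=False) as nc:
        for var in _ANDI_REQUIRED:
            if var not in nc.variables:
                raise ChromatogramFormatError(
                    f"{path}: missing required ANDI-MS variable {var!r}"
                )
        scan_time_s = np.array(nc.variables["scan_acquisition_time"][:], dtype=float)
        scan_index = np.array(nc.variables["scan_index"][:], dtype=np.int64)
        point_count = np.array(nc.variables["point_count"][:], dtype=np.int64)
        mass_values = np.array(nc.variables["mass_values"][:], dtype=float)
        intensity_values = np.array(nc.variables["intensity_values"][:], dtype=float)
        metadata = {}
        for key in ("instrument", "sample_id", "dataset_origin", "experiment_title"):
            if hasattr(nc, key):
                raw = getattr(nc, key)
                metadata[key] = raw.decode() if isinstance(raw, bytes) else str(raw)

    n_scans = scan_time_s.size
    if n_scans == 0:
        raise ChromatogramFormatError(f"{path}: file contains zero scans")

    mz_rounded = np.rint(mass_values).astype(int)
    if mz_rounded.size:
        lo, hi = int(mz_rounded.min()), int(mz_rounded.max())
    else:  # all-empty scans: fall back to the conventional full-scan range
        lo, hi = 50, 450
    if hi == lo:
        hi = lo + 1
    mz_axis = np.arange(lo, hi + 1)

    intensities = np.zeros((n_scans, mz_axis.size))
    for i in range(n_scans):
        start = int(scan_index[i])
        stop = start + int(point_count[i])
        cols = mz_rounded[start:stop] - lo
        np.add.at(intensities[i], cols, intensity_values[start:stop])

    return Chromatogram(scan_time_s / 60.0, mz_axis, intensities, metadata)


def write_cdf(chrom: Chromatogram, path) -> None:
    """Write an ANDI-MS netCDF file readable by :func:`read_cdf`.

    Zero-intensity bins are omitted from the per-scan centroid lists, so a
    read/write round trip is lossless on the unit m/z grid.
    """
    masses, intens, point_count, scan_index = [], [], [], []
    offset = 0
    for row in chrom.intensities:
        nz = np.nonzero(row)[0]
        scan_index.append(offset)
        point_count.append(nz.size)
        offset += nz.size
        masses.append(chrom.mz_axis[nz].astype(float))
        intens.append(row[nz])
    mass_values = np.concatenate(masses) if offset else np.zeros(0)
    intensity_values = np.concatenate(intens) if offset else np.zeros(0)

    with netcdf_file(str(path), "w") as nc:
        nc.dataset_origin = chrom.metadata.get("dataset_origin", "chromdecon")
        if "sample_id" in chrom.metadata:
            nc.sample_id = chrom.metadata["sample_id"]
        nc.createDimension("scan_number", chrom.n_scans)
        # netCDF-3 forbids zero-length dimensions; pad an all-zero run with
        # one sentinel point that carries zero intensity.
        n_points = max(int(offset), 1)
        nc.createDimension("point_number", n_points)
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = chrom.scan_times * 60.0
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = np.asarray(scan_index, dtype=np.int32)
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = np.asarray(point_count, dtype=np.int32)
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = (
            mass_values
            if offset
            else np.array([float(chrom.mz_axis[0])])
        )
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = intensity_values if offset else np.zeros(1)
        v = nc.createVariable("total_intensity", "d", ("scan_number",))
        v[:] = chrom.tic()


# ---------------------------------------------------------------------------
# NIST MSP text libraries
# ---------------------------------------------------------------------------


def read_msp(path) -> list:
    """Parse a NIST MSP text library into normalized :class:`LibrarySpectrum`.

    Accepts the common dialect: ``Name:`` starts an entry, ``Num Peaks:``
    announces the centroid list, and peak pairs are separated by ``;`` or
    whitespace. Each spectrum is normalized to base peak 999; entry order
    is preserved.
    """
    entries = []
    name = None
    retention_time = None
    num_peaks = None
    peaks: list = []
    in_peaks = False

    def flush():
        nonlocal name, retention_time, num_peaks, peaks, in_peaks
        if name is None:
            return
        if num_peaks is not None and len(peaks) != num_peaks:
            raise ChromatogramFormatError(
                f"entry {name!r}: Num Peaks is {num_peaks} but "
                f"{len(peaks)} pairs listed"
            )
        entries.append(
            LibrarySpectrum(name, list(peaks), retention_time).normalize()
        )
        name, retention_time, num_peaks, peaks, in_peaks = None, None, None, [], False

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("name:"):
                flush()
                name = line.split(":", 1)[1].strip()
            elif low.startswith(("retention_time:", "retentiontime:", "rt:")):
                try:
                    retention_time = float(line.split(":", 1)[1].strip())
                except ValueError:
                    pass
            elif low.startswith("num peaks:"):
                num_peaks = int(line.split(":", 1)[1].strip())
                in_peaks = True
            elif in_peaks:
                tokens = line.replace(";", " ").split()
                if len(tokens) % 2 != 0:
                    raise ChromatogramFormatError(
                        f"entry {name!r}: malformed peak line {line!r}"
                    )
                for mz_tok, int_tok in zip(tokens[::2], tokens[1::2]):
                    peaks.append((int(round(float(mz_tok))), float(int_tok)))
    flush()
    return entries


def write_msp(spectra, path) -> None:
    """Write spectra as a NIST MSP text library (one entry per spectrum)."""
    with open(path, "w") as fh:
        for spec in spectra:
            norm = spec.normalize()
            fh.write(f"Name: {norm.name}\n")
            if norm.retention_time is not None:
                fh.write(f"Retention_time: {norm.retention_time}\n")
            fh.write(f"Num Peaks: {len(norm.peaks)}\n")
            for mz, inten in norm.peaks:
                fh.write(f"{mz} {inten};\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Internal dense CSV dialect
# ---------------------------------------------------------------------------


def write_dense_csv(chrom: Chromatogram, path) -> None:
    """Dense dialect: header row = m/z bins, first column = scan time (min)."""
    with open(path, "w") as fh:
        fh.write("scan_time_min," + ",".join(str(m) for m in chrom.mz_axis) + "\n")
        for t, row in zip(chrom.scan_times, chrom.intensities):
            fh.write(f"{float(t)!r},"
                     + ",".join(repr(float(v)) for v in row) + "\n")
        if chrom.metadata:
            fh.write("#metadata," + json.dumps(chrom.metadata) + "\n")


def read_dense_csv(path) -> Chromatogram:
    metadata = {}
    times, rows = [], []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[0] != "scan_time_min":
            raise ChromatogramFormatError(f"{path}: not a dense chromatogram CSV")
        mz_axis = np.array([int(m) for m in header[1:]])
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#metadata,"):
                metadata = json.loads(line.split(",", 1)[1])
                continue
            parts = line.split(",")
            times.append(float(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    return Chromatogram(np.array(times), mz_axis, np.array(rows), metadata)
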
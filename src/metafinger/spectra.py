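"""Centroided mass spectra: the basic observable of ambient-MS fingerprinting.

A :class:`Spectrum` is one scan's centroided peak list — strictly increasing
m/z values with non-negative intensities — tagged with the ionization
polarity.  Ambient sources acquire several continuous scans per sample;
:func:`average_scans` collapses them into one representative spectrum using
the same mass-tolerance clustering rule that later defines matrix bins, so a
peak that drifts a few mDa between scans still contributes to a single
averaged peak.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Spectrum", "average_scans", "cluster_mz", "read_peak_list", "write_peak_list", "read_mzml"]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Spectrum:
    """One centroided scan.

    Parameters
    ----------
    mz
        Strictly increasing m/z values.
    intensity
        Non-negative intensities, same length as ``mz``.
    polarity
        ``"positive"`` or ``"negative"``.
    """

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = POSITIVE

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D")
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def __len__(self) -> int:
        return int(self.mz.size)


def cluster_mz(mz: np.ndarray, tolerance: float) -> np.ndarray:
    """Single-linkage mass clustering by the gap rule.

    Sorted m/z values are walked once; a gap larger than ``2 * tolerance``
    between consecutive values starts a new cluster.  This is the global,
    order-independent construction of a "±tolerance mass bin": any two peaks
    whose chain of neighbours never jumps more than the full bin width end up
    together.

    Parameters
    ----------
    mz
        Sorted 1-D array of m/z values.
    tolerance
        Half-width of a mass bin in Da (e.g. 0.005).

    Returns
    -------
    ndarray of int
        Cluster label per input value, labels increasing with m/z.
    """
    mz = np.asarray(mz, dtype=float)
    if mz.size == 0:
        return np.empty(0, dtype=int)
    breaks = np.diff(mz) > 2.0 * tolerance
    return np.concatenate([[0], np.cumsum(breaks)])


def average_scans(scans: Sequence[Spectrum], tolerance: float = 0.005) -> Spectrum:
    """Average continuous scans into one spectrum.

    Peaks pooled from every scan are clustered with :func:`cluster_mz`; each
    cluster yields one averaged peak whose m/z is the intensity-weighted mean
    of its members and whose intensity is the cluster's total intensity
    divided by the number of scans — a peak absent from a scan therefore
    counts as zero in that scan.

    Raises
    ------
    ValueError
        If no scans are given or polarities are mixed.
    """
    if len(scans) == 0:
        raise ValueError("need at least one scan")
    polarities = {s.polarity for s in scans}
    if len(polarities) > 1:
        raise ValueError("cannot average scans of mixed polarity")

    all_mz = np.concatenate([s.mz for s in scans])
    all_int = np.concatenate([s.intensity for s in scans])
    if all_mz.size == 0:
        return Spectrum(np.empty(0), np.empty(0), polarity=scans[0].polarity)

    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]
    labels = cluster_mz(all_mz, tolerance)
    n_clusters = labels[-1] + 1

    sum_int = np.bincount(labels, weights=all_int, minlength=n_clusters)
    sum_wmz = np.bincount(labels, weights=all_int * all_mz, minlength=n_clusters)
    counts = np.bincount(labels, minlength=n_clusters)
    # intensity-weighted centroid; plain mean if a cluster is all-zero intensity
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_mz = np.where(sum_int > 0, sum_wmz / sum_int,
                           np.bincount(labels, weights=all_mz, minlength=n_clusters) / counts)
    mean_int = sum_int / len(scans)
    order = np.argsort(mean_mz)
    return Spectrum(mean_mz[order], mean_int[order], polarity=scans[0].polarity)


def write_peak_list(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV (mz, intensity)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mz", "intensity"])
        for m, i in zip(spectrum.mz, spectrum.intensity):
            writer.writerow([f"{m:.6f}", f"{i:.6g}"])


def read_peak_list(path: str | Path, polarity: str = POSITIVE) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV peak list.

    A header row is detected and skipped if the first field is not numeric.
    Peaks are sorted by m/z; exact duplicate m/z values are summed.
    """
    mz: list[float] = []
    inten: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                m = float(row[0])
            except ValueError:
                continue  # header
            mz.append(m)
            inten.append(float(row[1]))
    mz_arr = np.asarray(mz)
    int_arr = np.asarray(inten)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    if mz_arr.size > 1:
        uniq, inverse = np.unique(mz_arr, return_inverse=True)
        if uniq.size < mz_arr.size:
            int_arr = np.bincount(inverse, weights=int_arr)
            mz_arr = uniq
    return Spectrum(mz_arr, int_arr, polarity=polarity)


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read centroided scans from an mzML file via pyteomics."""
    from pyteomics import mzml as _mzml

    out: list[Spectrum] = []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            pol = NEGATIVE if "negative scan" in scan else POSITIVE
            mz = np.asarray(scan["m/z array"], dtype=float)
            inten = np.asarray(scan["intensity array"], dtype=float)
            order = np.argsort(mz)
            out.append(Spectrum(mz[order], inten[order], polarity=pol))
    return out
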
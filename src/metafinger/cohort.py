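"""Synthetic ambient-MS cohorts with known ground truth.

This module emulates the statistical structure of a two-arm clinical
metabolic-fingerprinting study so the whole downstream pipeline can be
exercised against a known answer:

* a **tissue arm** of paired tumor (TNBC) and adjacent-normal (PNT)
  cryosection sampling points — by default 40 patients x 2 tissues x 3
  sampling points = 240 points;
* a **serum arm** of cases and healthy donors (by default 242 TNBC + 139
  HD = 381 samples) with pooled-serum QC injections inserted into the run
  sequence at a fixed spacing;
* per-sample **scan sets**: each sample yields several continuous centroided
  scans over a shared ion set, with designated marker ions multiplied by a
  ground-truth fold change in the case group, per-patient random effects,
  per-sample multiplicative noise and total-signal (TIC) variation, mild
  run-order drift, and bounded m/z jitter that keeps every ion inside its
  own mass bin;
* **raster line scans** over a rectangular region for imaging round-trips.

All randomness flows from one root seed through named substreams, so any
stage is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .spectra import POSITIVE, Spectrum

__all__ = [
    "CohortDesign",
    "SampleRecord",
    "generate_cohort",
    "generate_scan_set",
    "generate_raster",
    "split_by_patient",
    "records_to_manifest",
    "manifest_to_records",
    "simulate_peak_samples",
]

TISSUE, SERUM, QC = "tissue", "serum", "qc"
TNBC, PNT, HD = "TNBC", "PNT", "HD"

# substream tags for the named random streams hanging off the root seed
_STREAM_IONS = 0
_STREAM_PATIENT = 1
_STREAM_SAMPLE = 2


@dataclass(frozen=True)
class CohortDesign:
    """Study design and noise model for a synthetic cohort.

    Defaults mirror the emulated study: 40 patients with paired tissues
    sampled at 3 points each, a 242/139 case/control serum cohort, QC
    injections every 30 runs, and fingerprints of a few thousand ions over
    m/z 50-1,000.

    ``marker_spec`` lists ground-truth differential ions as
    ``(ion_index, fold_change)`` or ``(ion_index, fold_change, direction)``
    tuples; the multiplier applies to the case (TNBC) group on the linear
    intensity scale, before TIC scaling.
    """

    n_patients: int = 40
    points_per_tissue: int = 3
    n_tnbc_serum: int = 242
    n_hd_serum: int = 139
    n_ions: int = 3829
    mz_range: tuple[float, float] = (50.0, 1000.0)
    marker_spec: tuple[tuple, ...] = ()
    tic_cv: float = 0.2
    noise_sd: float = 0.3
    patient_effect_sd: float = 0.15
    qc_every: int = 30
    drift_slope: float = 1.0002
    mz_jitter: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "points_per_tissue", "n_tnbc_serum",
                     "n_hd_serum", "n_ions", "qc_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "mz_range", tuple(float(x) for x in self.mz_range))
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must satisfy low < high")
        for neg in ("tic_cv", "noise_sd", "patient_effect_sd", "mz_jitter"):
            if getattr(self, name := neg) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_slope <= 0:
            raise ValueError("drift_slope must be > 0")
        object.__setattr__(self, "marker_spec", tuple(tuple(m) for m in self.marker_spec))
        for spec in self.marker_spec:
            idx, fc = int(spec[0]), float(spec[1])
            if not 0 <= idx < self.n_ions:
                raise ValueError(f"marker ion index {idx} outside [0, {self.n_ions})")
            if fc <= 0:
                raise ValueError("fold change multipliers must be > 0")
            if len(spec) > 2:
                stated = spec[2]
                implied = "up" if fc > 1 else "down"
                if stated not in ("up", "down"):
                    raise ValueError(f"direction must be 'up' or 'down', got {stated!r}")
                if stated != implied:
                    raise ValueError(
                        f"marker {idx}: direction {stated!r} inconsistent with fold change {fc}")

    @property
    def marker_map(self) -> dict[int, dict]:
        """Ground truth: ion index -> fold change and direction."""
        return {
            int(m[0]): {"fold_change": float(m[1]),
                        "direction": "up" if float(m[1]) > 1 else "down"}
            for m in self.marker_spec
        }


@dataclass(frozen=True)
class SampleRecord:
    """One acquisition in the run sequence."""

    sample_id: str
    specimen: str        # tissue | serum | qc
    group: str           # TNBC | PNT | HD | QC
    patient_id: str      # empty for serum and QC samples
    run_index: int       # unique within its batch (tissue or serum sequence)
    polarity: str = POSITIVE

    def __post_init__(self) -> None:
        if self.specimen == TISSUE and not self.patient_id:
            raise ValueError("tissue samples must carry a patient_id")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@lru_cache(maxsize=8)
def _ion_params(design: CohortDesign) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-design ion set: (m/z centers, baseline intensities).

    Ion centers are drawn on a 0.025-Da grid so adjacent ions are separated
    by well over two bin widths and m/z jitter can never merge two ions into
    one mass bin.  Baselines are log-uniform over three orders of magnitude,
    mimicking the dynamic range of a metabolic fingerprint.
    """
    rng = _rng(design.seed, _STREAM_IONS)
    low, high = design.mz_range
    grid = np.arange(low + 0.05, high - 0.05, 0.025)
    if grid.size < design.n_ions:
        raise ValueError("mz_range too narrow for n_ions at 0.025 Da spacing")
    centers = np.sort(rng.choice(grid, size=design.n_ions, replace=False))
    baseline = 10.0 ** rng.uniform(2.0, 5.0, size=design.n_ions)
    return centers, baseline


def _fold_vector(design: CohortDesign) -> np.ndarray:
    fc = np.ones(design.n_ions)
    for idx, info in design.marker_map.items():
        fc[idx] = info["fold_change"]
    return fc


def generate_cohort(design: CohortDesign) -> tuple[list[SampleRecord], dict[int, dict]]:
    """Lay out the full run sequence and return it with the marker ground truth.

    The tissue and serum arms form two separate run sequences (batches);
    within each, every ``qc_every``-th run position (1-based) is a pooled QC
    injection, and real samples fill the remaining positions.  Tissue points
    alternate TNBC/PNT within each patient; serum cases and controls are
    interleaved, mirroring an alternating clinical run order.
    """
    tissue_payload: list[tuple[str, str, str, str]] = []
    for p in range(design.n_patients):
        pid = f"P{p + 1:03d}"
        for point in range(design.points_per_tissue):
            for grp in (TNBC, PNT):
                sid = f"T-{pid}-{grp}-{point + 1}"
                tissue_payload.append((sid, TISSUE, grp, pid))

    serum_payload: list[tuple[str, str, str, str]] = []
    n_case, n_ctrl = design.n_tnbc_serum, design.n_hd_serum
    i = j = 0
    while i < n_case or j < n_ctrl:
        if i < n_case:
            serum_payload.append((f"S-TNBC-{i + 1:03d}", SERUM, TNBC, ""))
            i += 1
        if j < n_ctrl:
            serum_payload.append((f"S-HD-{j + 1:03d}", SERUM, HD, ""))
            j += 1

    records: list[SampleRecord] = []
    for batch, payload in (("T", tissue_payload), ("S", serum_payload)):
        run = 0
        queue = iter(payload)
        pending = next(queue, None)
        n_qc = 0
        while pending is not None:
            if (run + 1) % design.qc_every == 0:
                n_qc += 1
                records.append(SampleRecord(f"{batch}-QC-{n_qc:02d}", QC, "QC", "", run))
            else:
                records.append(SampleRecord(pending[0], pending[1], pending[2], pending[3], run))
                pending = next(queue, None)
            run += 1
    return records, design.marker_map


def split_by_patient(
    records: Sequence[SampleRecord], n_train_patients: int = 25
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Patient-level train/test split of the tissue arm.

    All sampling points of one patient land on the same side, so the split
    never leaks paired tissue points across sets.  With the default design
    (40 patients, 3 points per tissue) and 25 training patients this yields
    150 training and 90 test points.
    """
    tissue = [r for r in records if r.specimen == TISSUE]
    patients = sorted({r.patient_id for r in tissue})
    if not 0 < n_train_patients < len(patients):
        raise ValueError("n_train_patients must split the patients into two non-empty sets")
    train_ids = set(patients[:n_train_patients])
    train = [r for r in tissue if r.patient_id in train_ids]
    test = [r for r in tissue if r.patient_id not in train_ids]
    return train, test


def generate_scan_set(
    record: SampleRecord, design: CohortDesign, n_scans: int = 10
) -> list[Spectrum]:
    """Simulate one sample's continuous scans.

    The per-sample expected intensity of ion *i* is::

        baseline_i x FC_i[group] x patient_i x noise_i x TIC x drift^run

    where ``FC_i`` applies only in the case (TNBC) group, ``patient_i`` is a
    per-patient log-normal effect shared by all of that patient's samples,
    ``noise_i`` is per-sample log-normal with sd ``noise_sd``, ``TIC`` is a
    mean-one log-normal scale with coefficient of variation ``tic_cv``, and
    drift compounds per run position.  Each scan then adds multiplicative
    jitter (sd ``noise_sd / 2``) and bounded m/z jitter.  QC samples are the
    deterministic mean of the case and control expected profiles, subject to
    drift only.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    centers, baseline = _ion_params(design)
    fc = _fold_vector(design)

    drift = design.drift_slope ** record.run_index
    if record.specimen == QC:
        level = baseline * (1.0 + fc) / 2.0 * drift
        scan_sd = 0.0
        rng = _rng(design.seed, _STREAM_SAMPLE, 1, record.run_index)
    else:
        level = baseline.copy()
        if record.group == TNBC:
            level = level * fc
        if record.patient_id:
            p_idx = int(record.patient_id.lstrip("P"))
            p_rng = _rng(design.seed, _STREAM_PATIENT, p_idx)
            level = level * np.exp(p_rng.normal(0.0, design.patient_effect_sd, design.n_ions))
        rng = _rng(design.seed, _STREAM_SAMPLE, 0 if record.specimen == TISSUE else 2,
                   record.run_index)
        if design.noise_sd > 0:
            level = level * np.exp(rng.normal(0.0, design.noise_sd, design.n_ions))
        if design.tic_cv > 0:
            sigma = math.sqrt(math.log(1.0 + design.tic_cv ** 2))
            level = level * math.exp(rng.normal(-0.5 * sigma * sigma, sigma))
        level = level * drift
        scan_sd = design.noise_sd / 2.0

    scans: list[Spectrum] = []
    for _ in range(n_scans):
        inten = level
        if scan_sd > 0:
            inten = level * np.exp(rng.normal(0.0, scan_sd, design.n_ions))
        mz = centers
        if design.mz_jitter > 0:
            mz = centers + rng.uniform(-design.mz_jitter, design.mz_jitter, design.n_ions)
        scans.append(Spectrum(mz, inten, polarity=record.polarity))
    return scans


def generate_raster(
    width_mm: float,
    height_mm: float,
    raster_speed: float,
    line_spacing: float,
    scan_rate: float,
    pattern: Callable[[float, float], float],
    target_mz: float = 175.1190,
    polarity: str = POSITIVE,
) -> list[tuple[int, float, Spectrum]]:
    """Simulate a DESI-style line-by-line raster over a rectangular region.

    The stage moves at ``raster_speed`` (mm/s) along each line while the MS
    acquires ``scan_rate`` scans per second, giving an along-track pixel
    width of ``raster_speed / scan_rate``; lines are ``line_spacing`` mm
    apart.  Each scan carries the target ion at the intensity of ``pattern``
    evaluated at that pixel's center.

    Returns a list of ``(line_index, scan_time_s, Spectrum)`` triples.
    """
    for name, value in (("width_mm", width_mm), ("height_mm", height_mm),
                        ("raster_speed", raster_speed), ("line_spacing", line_spacing),
                        ("scan_rate", scan_rate)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    pixel_width = raster_speed / scan_rate
    n_lines = math.ceil(height_mm / line_spacing)
    scans_per_line = math.ceil(width_mm / pixel_width)
    out: list[tuple[int, float, Spectrum]] = []
    for r in range(n_lines):
        y = (r + 0.5) * line_spacing
        for c in range(scans_per_line):
            t = (c + 0.5) / scan_rate
            x = raster_speed * t
            inten = float(pattern(x, y))
            out.append((r, t, Spectrum([target_mz], [max(inten, 0.0)], polarity=polarity)))
    return out


def records_to_manifest(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Sample records as a manifest table with the fixed column order."""
    return pd.DataFrame(
        [(r.sample_id, r.specimen, r.group, r.patient_id, r.run_index, r.polarity)
         for r in records],
        columns=["sample_id", "specimen", "group", "patient_id", "run_index", "polarity"],
    )


def manifest_to_records(manifest: pd.DataFrame) -> list[SampleRecord]:
    man = manifest.fillna({"patient_id": ""})
    return [
        SampleRecord(str(row.sample_id), str(row.specimen), str(row.group),
                     str(row.patient_id), int(row.run_index), str(row.polarity))
        for row in man.itertuples(index=False)
    ]


def simulate_peak_samples(
    design: CohortDesign,
    records: Sequence[SampleRecord],
    n_scans: int = 10,
    tolerance: float = 0.005,
) -> dict[str, Spectrum]:
    """Scan-set simulation + averaging for many samples at once.

    Convenience wrapper returning ``sample_id -> averaged Spectrum``, ready
    for :func:`metafinger.peakmatrix.bin_to_matrix`.
    """
    from .spectra import average_scans

    return {
        r.sample_id: average_scans(generate_scan_set(r, design, n_scans), tolerance)
        for r in records
    }
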
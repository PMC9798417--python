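"""From averaged spectra to a normalized samples x mass-bin matrix.

The fingerprinting pipeline reduces each sample to one averaged spectrum,
then aligns all samples onto a common feature axis of *mass bins*: groups of
observed m/z values within a fixed Da tolerance (default ±0.005 Da), built
by global single-linkage clustering with a gap rule so the result is
deterministic and independent of sample order.  The raw matrix is
TIC-normalized row-wise (each sample divided by its mean peak intensity),
then natural-log transformed and autoscaled column-wise (mean 0, sd 1) to
remove the magnitude bias of high-abundance ions before modelling.

QC injections interspersed in the run sequence quantify instrument
stability: per-bin relative standard deviation across QC samples and a
rank correlation of QC intensity with run order (drift).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import QC, SampleRecord
from .spectra import Spectrum, cluster_mz

__all__ = [
    "PeakMatrix",
    "bin_to_matrix",
    "tic_normalize",
    "log_autoscale",
    "qc_report",
    "concat_polarities",
    "write_matrix",
    "read_matrix",
]

logger = logging.getLogger(__name__)

RAW = "raw"
TIC_NORMALIZED = "tic_normalized"
LOG_SCALED = "log_scaled"


@dataclass
class PeakMatrix:
    """Samples x mass-bin intensity matrix with metadata.

    ``stage`` tracks the processing state (``raw`` -> ``tic_normalized`` ->
    ``log_scaled``) so each transform can refuse out-of-order application.
    ``bin_mz`` holds one representative (intensity-weighted mean) m/z per
    bin; ``bin_ids`` are stable string identifiers, tagged with polarity
    when matrices from the two ionization modes are concatenated.
    """

    values: np.ndarray
    bin_mz: np.ndarray
    samples: list[SampleRecord]
    stage: str = RAW
    bin_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_mz = np.asarray(self.bin_mz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bins)")
        if self.values.shape[0] != len(self.samples):
            raise ValueError("row count must equal number of sample records")
        if self.values.shape[1] != self.bin_mz.size:
            raise ValueError("column count must equal bin_mz length")
        if self.bin_ids is None:
            pol = {s.polarity for s in self.samples}
            tag = pol.pop()[:3] if len(pol) == 1 else "mix"
            self.bin_ids = [f"{tag}_{mz:.4f}" for mz in self.bin_mz]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    def subset_samples(self, keep: Sequence[bool] | np.ndarray) -> "PeakMatrix":
        keep = np.asarray(keep, dtype=bool)
        return PeakMatrix(self.values[keep], self.bin_mz,
                          [s for s, k in zip(self.samples, keep) if k],
                          stage=self.stage, bin_ids=list(self.bin_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bin_ids)


def bin_to_matrix(
    spectra: Mapping[str, Spectrum] | Mapping[SampleRecord, Spectrum],
    tolerance: float = 0.005,
    samples: Sequence[SampleRecord] | None = None,
) -> PeakMatrix:
    """Align sample spectra on a common mass-bin axis.

    Bins come from single-linkage clustering of the pooled m/z values of all
    samples: a gap greater than twice the tolerance between consecutive
    sorted m/z values starts a new bin.  Each sample's peak intensities are
    summed into their bins; a sample with no peak in a bin contributes 0.

    Parameters
    ----------
    spectra
        ``sample_id -> Spectrum`` (with ``samples`` supplying the matching
        records) or ``SampleRecord -> Spectrum``.
    tolerance
        Mass-bin half width in Da.
    samples
        Sample records aligned with ``spectra`` keys when those are ids;
        minimal records are fabricated if omitted.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to bin")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")

    keys = list(spectra.keys())
    if isinstance(keys[0], SampleRecord):
        records = list(keys)
        spec_list = [spectra[k] for k in keys]
    else:
        if samples is not None:
            by_id = {s.sample_id: s for s in samples}
            records = [by_id[k] for k in keys]
        else:
            records = [SampleRecord(str(k), "serum", "NA", "", i)
                       for i, k in enumerate(keys)]
        spec_list = [spectra[k] for k in keys]

    all_mz = np.concatenate([s.mz for s in spec_list])
    all_int = np.concatenate([s.intensity for s in spec_list])
    all_row = np.concatenate([np.full(len(s), i) for i, s in enumerate(spec_list)])
    if all_mz.size == 0:
        raise ValueError("all spectra are empty; nothing to bin")

    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_row = all_mz[order], all_int[order], all_row[order]
    labels = cluster_mz(all_mz, tolerance)
    n_bins = labels[-1] + 1

    values = np.zeros((len(spec_list), n_bins))
    np.add.at(values, (all_row.astype(int), labels), all_int)

    sum_int = np.bincount(labels, weights=all_int, minlength=n_bins)
    sum_wmz = np.bincount(labels, weights=all_int * all_mz, minlength=n_bins)
    counts = np.bincount(labels, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_mz = np.where(sum_int > 0, sum_wmz / sum_int,
                          np.bincount(labels, weights=all_mz, minlength=n_bins) / counts)
    return PeakMatrix(values, bin_mz, records, stage=RAW)


def tic_normalize(pm: PeakMatrix, use_sum: bool = False) -> PeakMatrix:
    """Divide each sample by its average (or total) ion current.

    The per-sample normalizer is the mean peak intensity over all bins
    (``use_sum=True`` divides by the plain sum instead).  All-zero samples
    are left untouched with a warning.
    """
    if pm.stage != RAW:
        raise ValueError(f"tic_normalize expects a raw matrix, got stage={pm.stage!r}")
    norm = pm.values.sum(axis=1) if use_sum else pm.values.mean(axis=1)
    zero = norm == 0
    if zero.any():
        ids = [s for s, z in zip(pm.sample_ids, zero) if z]
        logger.warning("all-zero sample(s) left unnormalized: %s", ", ".join(ids))
        warnings.warn(f"all-zero sample(s) left unnormalized: {ids}", stacklevel=2)
    safe = np.where(zero, 1.0, norm)
    return PeakMatrix(pm.values / safe[:, None], pm.bin_mz, list(pm.samples),
                      stage=TIC_NORMALIZED, bin_ids=list(pm.bin_ids))


def log_autoscale(pm: PeakMatrix, epsilon: float | None = None) -> PeakMatrix:
    """Natural-log transform, then per-bin centering and unit-variance scaling.

    ``epsilon`` (added before the log so zeros are defined) defaults to half
    the smallest nonzero value in the matrix.  Standard deviations use the
    n-1 denominator; constant bins are mapped to all-zero columns.
    """
    if pm.stage != TIC_NORMALIZED:
        raise ValueError(f"log_autoscale expects a tic_normalized matrix, got {pm.stage!r}")
    if np.any(pm.values < 0):
        raise ValueError("negative intensities cannot be log transformed")
    if epsilon is None:
        nonzero = pm.values[pm.values > 0]
        epsilon = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    logged = np.log(pm.values + epsilon)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1) if logged.shape[0] > 1 else np.zeros(logged.shape[1])
    scaled = np.where(sd > 0, (logged - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return PeakMatrix(scaled, pm.bin_mz, list(pm.samples),
                      stage=LOG_SCALED, bin_ids=list(pm.bin_ids))


def qc_report(pm: PeakMatrix, rsd_threshold: float = 0.30) -> dict:
    """Instrument-stability summary from interspersed QC samples.

    Returns a dict with a per-bin table (``rsd`` = sd/mean across QC rows,
    ``drift_spearman`` = Spearman correlation of QC intensity with run
    order) and the fraction of bins whose RSD falls below the threshold.
    """
    qc_mask = np.array([s.specimen == QC for s in pm.samples])
    if qc_mask.sum() < 2:
        raise ValueError("qc_report needs at least 2 QC samples")
    qc_vals = pm.values[qc_mask]
    run_idx = np.array([s.run_index for s in pm.samples])[qc_mask]

    mean = qc_vals.mean(axis=0)
    sd = qc_vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rsd = np.where(mean > 0, sd / mean, np.nan)

    drift = np.full(pm.values.shape[1], np.nan)
    for j in range(pm.values.shape[1]):
        col = qc_vals[:, j]
        if np.ptp(col) > 0 and np.ptp(run_idx) > 0:
            drift[j] = stats.spearmanr(run_idx, col).statistic
        elif np.ptp(col) == 0:
            drift[j] = 0.0
    table = pd.DataFrame({"bin_mz": pm.bin_mz, "rsd": rsd, "drift_spearman": drift},
                         index=pm.bin_ids)
    return {
        "table": table,
        "n_qc": int(qc_mask.sum()),
        "rsd_threshold": rsd_threshold,
        "fraction_bins_below_threshold": float(np.mean(rsd[np.isfinite(rsd)] < rsd_threshold))
        if np.isfinite(rsd).any() else float("nan"),
    }


def concat_polarities(pos: PeakMatrix, neg: PeakMatrix) -> PeakMatrix:
    """Column-wise concatenation of matrices acquired in the two modes.

    Samples must match by id and stage; bin ids keep their polarity tags so
    features remain distinguishable after the merge.
    """
    if pos.stage != neg.stage:
        raise ValueError("stages differ between polarity matrices")
    if pos.sample_ids != neg.sample_ids:
        raise ValueError("sample sets differ between polarity matrices")
    return PeakMatrix(
        np.hstack([pos.values, neg.values]),
        np.concatenate([pos.bin_mz, neg.bin_mz]),
        list(pos.samples),
        stage=pos.stage,
        bin_ids=list(pos.bin_ids) + list(neg.bin_ids),
    )


def write_matrix(pm: PeakMatrix, path: str | Path) -> None:
    """Write a PeakMatrix as TSV plus a JSON sidecar (<path>.json).

    Full float precision is preserved so a read-back is bit-identical.
    """
    path = Path(path)
    frame = pm.to_frame()
    frame.to_csv(path, sep="\t", float_format="%.17g", index_label="sample_id")
    sidecar = {
        "stage": pm.stage,
        "bin_mz": [float(x) for x in pm.bin_mz],
        "bin_ids": list(pm.bin_ids),
        "samples": [
            {"sample_id": s.sample_id, "specimen": s.specimen, "group": s.group,
             "patient_id": s.patient_id, "run_index": s.run_index, "polarity": s.polarity}
            for s in pm.samples
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> PeakMatrix:
    """Read a PeakMatrix written by :func:`write_matrix`."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = [SampleRecord(**s) for s in sidecar["samples"]]
    return PeakMatrix(frame.to_numpy(), np.asarray(sidecar["bin_mz"]), samples,
                      stage=sidecar["stage"], bin_ids=sidecar["bin_ids"])
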
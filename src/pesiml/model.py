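"""Core domain types for the PESI-MS tissue-classification pipeline.

The pipeline's objects mirror the stages of a probe-electrospray (PESI)
acquisition on homogenized liver tissue: a 2-minute run of full-scan
continuum spectra (:class:`Acquisition`), 10-second averaged windows
(:class:`FragmentSpectrum`), centroided peak lists (:class:`PeakList`),
and the aligned, TIC-normalized fragment-by-bin matrix
(:class:`FeatureMatrix`) fed to the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_LABELS",
    "COHORTS",
    "TUMOUR_LABELS",
    "MZ_MIN",
    "MZ_MAX",
    "SampleRecord",
    "Acquisition",
    "FragmentSpectrum",
    "PeakList",
    "FeatureMatrix",
    "PipelineConfig",
    "ROW_META_COLUMNS",
]

TISSUE_LABELS = ("HCC", "MFCCC", "NONTUMOUR")
TUMOUR_LABELS = frozenset({"HCC", "MFCCC"})
COHORTS = ("HCC_cohort", "MFCCC_cohort")

# Instrument mass range (single-quadrupole, positive mode).
MZ_MIN = 10.0
MZ_MAX = 2000.0

ROW_META_COLUMNS = ("sample_id", "patient_id", "fragment_index", "tissue_label", "cohort")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class SampleRecord:
    """Identity and pathology label of one tissue sample.

    ``cohort`` records which study arm (HCC or MFCCC patients) the sample
    belongs to; it is metadata for task selection only and is never used
    as a model feature.  Non-tumour samples occur in either cohort.
    """

    sample_id: str
    patient_id: str
    tissue_label: str
    cohort: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.tissue_label not in TISSUE_LABELS:
            raise ValidationError(
                f"unknown tissue_label {self.tissue_label!r} for sample "
                f"{self.sample_id!r}; expected one of {TISSUE_LABELS}"
            )
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"unknown cohort {self.cohort!r} for sample {self.sample_id!r}; "
                f"expected one of {COHORTS}"
            )


@dataclass
class Acquisition:
    """One sample's 2-minute run of time-stamped continuum scans.

    ``intensities`` is a (n_scans, n_mz) array; row *i* is the profile
    spectrum recorded at ``times[i]`` seconds over the shared ``mz_axis``.
    """

    sample: SampleRecord
    mz_axis: np.ndarray
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mz_axis.ndim != 1 or not np.all(np.diff(self.mz_axis) > 0):
            raise ValidationError("mz_axis must be 1-D and strictly increasing")
        if self.mz_axis[0] < MZ_MIN or self.mz_axis[-1] > MZ_MAX:
            raise ValidationError(
                f"mz_axis must lie within [{MZ_MIN}, {MZ_MAX}] Da"
            )
        if self.intensities.shape != (self.times.size, self.mz_axis.size):
            raise ValidationError(
                f"intensities shape {self.intensities.shape} does not match "
                f"(n_scans={self.times.size}, n_mz={self.mz_axis.size})"
            )
        bad = np.flatnonzero(np.diff(self.times) <= 0)
        if bad.size:
            raise ValidationError(
                f"scan times must be strictly increasing; violation at scan index {bad[0] + 1}"
            )
        if self.times.size and (self.times[0] < 0 or self.times[-1] >= 120.0 + 1e-9):
            raise ValidationError("scan times must lie in [0, 120) s")
        neg = np.argwhere(self.intensities < 0)
        if neg.size:
            raise ValidationError(
                f"negative intensity at scan index {int(neg[0, 0])}"
            )

    @property
    def n_scans(self) -> int:
        return int(self.times.size)


@dataclass
class FragmentSpectrum:
    """Average spectrum of one 10-second acquisition window."""

    sample_id: str
    fragment_index: int
    mz_axis: np.ndarray
    intensities: np.ndarray
    n_scans_averaged: int

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not 0 <= self.fragment_index <= 11:
            raise ValidationError(
                f"fragment_index {self.fragment_index} outside [0, 11]"
            )
        if self.n_scans_averaged <= 0:
            raise ValidationError("n_scans_averaged must be positive")
        if np.any(self.intensities < 0):
            raise ValidationError("fragment intensities must be >= 0")


@dataclass
class PeakList:
    """Centroided peaks of one fragment: ascending m/z, positive intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D and equally sized")
        if self.mz.size:
            if not np.all(np.diff(self.mz) > 0):
                raise ValidationError("peak m/z values must be strictly increasing")
            if self.mz[0] < MZ_MIN or self.mz[-1] > MZ_MAX:
                raise ValidationError(f"peak m/z outside [{MZ_MIN}, {MZ_MAX}] Da")
            if np.any(self.intensity <= 0):
                raise ValidationError("peak intensities must be > 0")

    def __len__(self) -> int:
        return int(self.mz.size)


# Tolerance on TIC-normalized row sums.
ROW_SUM_TOL = 1e-9


@dataclass
class FeatureMatrix:
    """Fragments x aligned-m/z-bins matrix with per-row metadata.

    ``row_meta`` is a DataFrame with columns ``sample_id``, ``patient_id``,
    ``fragment_index``, ``tissue_label`` and ``cohort``, one row per
    fragment, aligned with the rows of ``X``.
    """

    bin_mz: np.ndarray
    X: np.ndarray
    row_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_mz = np.asarray(self.bin_mz, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D")
        if self.X.shape[1] != self.bin_mz.size:
            raise ValidationError(
                f"X has {self.X.shape[1]} columns but bin_mz has {self.bin_mz.size} entries"
            )
        if self.X.shape[0] != len(self.row_meta):
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but row_meta has {len(self.row_meta)}"
            )
        missing = [c for c in ROW_META_COLUMNS if c not in self.row_meta.columns]
        if missing:
            raise ValidationError(f"row_meta missing columns {missing}")
        if self.bin_mz.size > 1 and not np.all(np.diff(self.bin_mz) > 0):
            raise ValidationError("bin_mz must be strictly increasing")
        if self.normalized and self.X.shape[0]:
            sums = self.X.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
            if bad.size:
                raise ValidationError(
                    f"matrix flagged normalized but row {int(bad[0])} sums to {sums[bad[0]]!r}"
                )

    @property
    def n_rows(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.bin_mz.size)

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        """Row-subset view preserving metadata alignment."""
        mask = np.asarray(mask)
        return FeatureMatrix(
            bin_mz=self.bin_mz,
            X=self.X[mask],
            row_meta=self.row_meta.loc[mask].reset_index(drop=True),
            normalized=self.normalized,
        )


@dataclass
class PipelineConfig:
    """Tunable constants of the acquisition-to-verdict pipeline.

    Defaults follow the published protocol: 10-second windows, 12 exported
    fragments of which the last two are discarded, 0.5 Da alignment
    tolerance, and 10-fold patient-grouped cross-validation.
    """

    fragment_seconds: float = 10.0
    n_fragments_exported: int = 12
    n_fragments_kept: int = 10
    align_tol_da: float = 0.5
    noise_k: float = 5.0
    min_rel_intensity: float = 0.001
    k_folds: int = 10
    vote_threshold_rule: str = "majority"  # verdict concordant iff n_correct >= ceil(n/2)
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    rf_n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments_kept > self.n_fragments_exported:
            raise ValidationError(
                "n_fragments_kept must be <= n_fragments_exported "
                f"({self.n_fragments_kept} > {self.n_fragments_exported})"
            )
        if self.align_tol_da <= 0:
            raise ValidationError("align_tol_da must be > 0")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.fragment_seconds <= 0:
            raise ValidationError("fragment_seconds must be > 0")
        if self.vote_threshold_rule != "majority":
            raise ValidationError(
                f"unknown vote_threshold_rule {self.vote_threshold_rule!r}"
            )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def with_overrides(self, overrides: Mapping[str, object]) -> "PipelineConfig":
        unknown = sorted(set(overrides) - set(self.field_names()))
        if unknown:
            raise ValidationError(
                f"unknown config keys {unknown}; valid keys are {sorted(self.field_names())}"
            )
        return replace(self, **overrides)
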
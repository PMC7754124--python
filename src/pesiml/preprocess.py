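"""Raw acquisitions -> TIC-normalized, peak-aligned fragment feature matrix.

Stages: split each 2-minute acquisition into 10-second windows and average
the scans of each window (the last two windows are discarded for signal
consistency); centroid each averaged continuum spectrum into a peak list;
align all peak lists jointly into shared m/z bins with a 0.5 Da tolerance;
normalize every fragment row on its total ion current.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ROW_META_COLUMNS,
    Acquisition,
    FeatureMatrix,
    FragmentSpectrum,
    PeakList,
    PipelineConfig,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["split_fragments", "centroid", "align_peaks", "tic_normalize",
           "preprocess_cohort"]


def split_fragments(
    acq: Acquisition,
    fragment_seconds: float = 10.0,
    n_exported: int = 12,
    n_kept: int = 10,
) -> list[FragmentSpectrum]:
    """Average scans within consecutive windows; return the first ``n_kept``.

    A scan at time *t* belongs to window ``floor(t / fragment_seconds)``.
    With the defaults, windows 0-11 are formed and windows 10-11 (the
    degraded tail of the run) are dropped.
    """
    idx = np.floor(acq.times / fragment_seconds).astype(int)
    out = []
    for w in range(n_kept):
        mask = idx == w
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(
                f"sample {acq.sample.sample_id}: no scans in kept window {w}"
            )
        out.append(
            FragmentSpectrum(
                sample_id=acq.sample.sample_id,
                fragment_index=w,
                mz_axis=acq.mz_axis,
                intensities=acq.intensities[mask].mean(axis=0),
                n_scans_averaged=n,
            )
        )
    return out


def centroid(
    fragment: FragmentSpectrum,
    noise_k: float = 5.0,
    min_rel_intensity: float = 0.001,
) -> PeakList:
    """Pick peaks from one averaged continuum spectrum.

    A grid point is a peak iff it is a strict local maximum, its intensity
    is at least ``noise_k`` times the MAD of the whole fragment, and at
    least ``min_rel_intensity`` times the base peak.  Each peak's m/z is
    refined as the intensity-weighted centroid of the three grid points
    around the maximum.
    """
    y = fragment.intensities
    if y.size < 3 or not np.any(y > 0):
        return PeakList(mz=np.empty(0), intensity=np.empty(0))
    mad = np.median(np.abs(y - np.median(y)))
    floor = max(noise_k * mad, min_rel_intensity * y.max())
    inner = y[1:-1]
    is_max = (inner > y[:-2]) & (inner > y[2:]) & (inner >= floor)
    apex = np.flatnonzero(is_max) + 1
    if apex.size == 0:
        return PeakList(mz=np.empty(0), intensity=np.empty(0))
    x = fragment.mz_axis
    tri = np.stack([y[apex - 1], y[apex], y[apex + 1]])
    tri_mz = np.stack([x[apex - 1], x[apex], x[apex + 1]])
    mz_ref = (tri * tri_mz).sum(axis=0) / tri.sum(axis=0)
    order = np.argsort(mz_ref)
    return PeakList(mz=mz_ref[order], intensity=y[apex][order])


def align_peaks(peaklists: Sequence[PeakList], tol_da: float = 0.5) -> FeatureMatrix:
    """Pool all peaks and bin them with the single-linkage gap rule.

    All peaks from all fragments are sorted by m/z; a new bin starts
    wherever the gap between consecutive pooled m/z values exceeds
    ``tol_da``.  Consecutive member gaps within a bin are therefore
    always <= ``tol_da`` although a chained bin may span more.  A
    fragment's value in a bin is the *sum* of its member peaks (conserving
    TIC); the bin centroid is the intensity-weighted mean m/z.

    Returns an unnormalized :class:`FeatureMatrix` whose ``row_meta``
    carries only ``sample_id`` placeholders; callers that know the
    manifest attach full metadata (see :func:`preprocess_cohort`).
    """
    if not any(len(pl) for pl in peaklists):
        raise ValidationError("align_peaks needs at least one non-empty PeakList")
    all_mz = np.concatenate([pl.mz for pl in peaklists])
    all_int = np.concatenate([pl.intensity for pl in peaklists])
    all_row = np.concatenate(
        [np.full(len(pl), i, dtype=int) for i, pl in enumerate(peaklists)]
    )
    order = np.argsort(all_mz, kind="stable")
    mz_s, int_s, row_s = all_mz[order], all_int[order], all_row[order]
    # bin id increments at every gap > tol
    new_bin = np.empty(mz_s.size, dtype=bool)
    new_bin[0] = True
    new_bin[1:] = np.diff(mz_s) > tol_da
    bin_id = np.cumsum(new_bin) - 1
    n_bins = int(bin_id[-1]) + 1

    X = np.zeros((len(peaklists), n_bins))
    np.add.at(X, (row_s, bin_id), int_s)
    wsum = np.bincount(bin_id, weights=int_s * mz_s, minlength=n_bins)
    tot = np.bincount(bin_id, weights=int_s, minlength=n_bins)
    bin_mz = wsum / tot

    # centroids of gap-rule bins are separated by > 0, but enforce ascending
    srt = np.argsort(bin_mz)
    meta = pd.DataFrame(
        {
            "sample_id": [f"row{i}" for i in range(len(peaklists))],
            "patient_id": "",
            "fragment_index": 0,
            "tissue_label": "HCC",
            "cohort": "HCC_cohort",
        }
    )
    return FeatureMatrix(bin_mz=bin_mz[srt], X=X[:, srt], row_meta=meta, normalized=False)


def tic_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide every row by its own total ion current (row sum)."""
    sums = fm.X.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        r = fm.row_meta.iloc[int(bad[0])]
        raise ValidationError(
            f"cannot TIC-normalize zero-sum row: sample {r['sample_id']} "
            f"fragment {r['fragment_index']}"
        )
    return FeatureMatrix(
        bin_mz=fm.bin_mz,
        X=fm.X / sums[:, None],
        row_meta=fm.row_meta.reset_index(drop=True),
        normalized=True,
    )


def preprocess_cohort(
    acquisitions: Iterable[Acquisition],
    config: PipelineConfig | None = None,
) -> FeatureMatrix:
    """Full preprocessing of a cohort of acquisitions.

    split -> centroid -> align (jointly across all fragments of all
    samples) -> TIC-normalize.  Accepts any iterable (including the lazy
    simulator stream); peak lists are kept, raw scans are not, so memory
    stays bounded at study scale.
    """
    cfg = config or PipelineConfig()
    peaklists: list[PeakList] = []
    meta_rows: list[tuple] = []
    for acq in acquisitions:
        try:
            frags = split_fragments(
                acq, cfg.fragment_seconds, cfg.n_fragments_exported, cfg.n_fragments_kept
            )
            for fr in frags:
                peaklists.append(centroid(fr, cfg.noise_k, cfg.min_rel_intensity))
                s = acq.sample
                meta_rows.append(
                    (s.sample_id, s.patient_id, fr.fragment_index, s.tissue_label, s.cohort)
                )
        except ValidationError as exc:
            raise ValidationError(f"sample {acq.sample.sample_id}: {exc}") from exc
    if not meta_rows:
        raise ValidationError("no acquisitions to preprocess")
    fm = align_peaks(peaklists, cfg.align_tol_da)
    fm.row_meta = pd.DataFrame(meta_rows, columns=list(ROW_META_COLUMNS))
    logger.info(
        "preprocessed %d fragments from %d samples into %d bins",
        fm.n_rows, len(meta_rows) // cfg.n_fragments_kept, fm.n_bins,
    )
    return tic_normalize(fm)
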
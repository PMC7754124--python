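"""Readers and writers for the pipeline's plain-text artefacts.

The vendor export schema is proprietary, so this package defines its own
diffable text formats (documented in the README):

* **manifest** — CSV with columns ``sample_id, patient_id, tissue_label,
  cohort``;
* **scan table** — tab-keyed text, one acquisition per file: four metadata
  lines, an ``mz_axis`` line, then one ``scan`` line per spectrum;
* **feature matrix** — TSV with metadata columns followed by one column per
  aligned m/z bin, plus a ``# normalized=`` comment header;
* **config** — YAML mapping onto :class:`~pesiml.model.PipelineConfig`.

mzML import is optional sugar mapped onto :class:`~pesiml.model.Acquisition`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    ROW_META_COLUMNS,
    Acquisition,
    FeatureMatrix,
    PipelineConfig,
    SampleRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "patient_id", "tissue_label", "cohort")

# %.17g round-trips IEEE doubles exactly through text.
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- manifest

def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read and validate a sample manifest CSV."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"duplicate sample_id {dup.iloc[0]!r} in manifest {path}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    patient_id=row["patient_id"],
                    tissue_label=row["tissue_label"],
                    cohort=row["cohort"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"manifest {path} row {i}: {exc}") from exc
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.patient_id, r.tissue_label, r.cohort) for r in records],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, index=False)


# -------------------------------------------------------------- scan table

SCAN_TABLE_MAGIC = "# pesiml scan table v1"


def write_scan_table(acq: Acquisition, path: str | Path) -> None:
    """Write one acquisition as tab-keyed text (losslessly re-readable)."""
    with open(path, "w") as fh:
        fh.write(SCAN_TABLE_MAGIC + "\n")
        s = acq.sample
        fh.write(f"sample_id\t{s.sample_id}\n")
        fh.write(f"patient_id\t{s.patient_id}\n")
        fh.write(f"tissue_label\t{s.tissue_label}\n")
        fh.write(f"cohort\t{s.cohort}\n")
        axis = " ".join(_FLOAT_FMT % v for v in acq.mz_axis)
        fh.write(f"mz_axis\t{axis}\n")
        for t, row in zip(acq.times, acq.intensities):
            vals = " ".join(_FLOAT_FMT % v for v in row)
            fh.write(f"scan\t{_FLOAT_FMT % t}\t{vals}\n")


def read_scan_table(path: str | Path) -> Acquisition:
    """Parse a scan-table file into a validated :class:`Acquisition`."""
    meta: dict[str, str] = {}
    mz_axis: np.ndarray | None = None
    times: list[float] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("\t")
            if key == "mz_axis":
                mz_axis = np.asarray(rest.split(), dtype=float)
            elif key == "scan":
                t_str, _, vals = rest.partition("\t")
                times.append(float(t_str))
                row = np.asarray(vals.split(), dtype=float)
                if mz_axis is None:
                    raise ValidationError(
                        f"{path}:{lineno}: scan line before mz_axis"
                    )
                if row.size != mz_axis.size:
                    raise ValidationError(
                        f"{path}: scan index {len(rows)} has {row.size} values, "
                        f"axis has {mz_axis.size}"
                    )
                rows.append(row)
            elif key in ("sample_id", "patient_id", "tissue_label", "cohort"):
                meta[key] = rest
            else:
                raise ValidationError(f"{path}:{lineno}: unknown line key {key!r}")
    if mz_axis is None:
        raise ValidationError(f"{path}: missing mz_axis line")
    missing = [k for k in ("sample_id", "patient_id", "tissue_label", "cohort") if k not in meta]
    if missing:
        raise ValidationError(f"{path}: missing metadata lines {missing}")
    sample = SampleRecord(**meta)
    intensities = np.vstack(rows) if rows else np.empty((0, mz_axis.size))
    return Acquisition(
        sample=sample, mz_axis=mz_axis, times=np.asarray(times), intensities=intensities
    )


def _decode_binary_array(node, nsmap) -> np.ndarray:
    import base64
    import zlib

    accessions = {cv.get("accession") for cv in node.findall("mzml:cvParam", nsmap)}
    raw = base64.b64decode((node.findtext("mzml:binary", "", nsmap) or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, sample: SampleRecord) -> Acquisition:
    """Map an mzML file onto an :class:`Acquisition` (optional import path).

    Minimal reader for profile-mode MS1 spectra (64/32-bit float arrays,
    optionally zlib-compressed).  Scans whose m/z array differs from the
    first scan's are linearly interpolated onto that first axis; scan
    start times are converted to seconds.
    """
    from lxml import etree

    ns = {"mzml": "http://psi.hupo.org/ms/mzml"}
    tree = etree.parse(str(path))
    times, rows = [], []
    mz_axis: np.ndarray | None = None
    for spec in tree.iterfind(".//mzml:spectrum", ns):
        params = {cv.get("accession"): cv for cv in spec.findall("mzml:cvParam", ns)}
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", ""):
            continue
        t_node = spec.find(".//mzml:scan/mzml:cvParam[@accession='MS:1000016']", ns)
        if t_node is None:
            raise ValidationError(f"{path}: spectrum without scan start time")
        t = float(t_node.get("value"))
        if "min" in (t_node.get("unitName") or "minute"):
            t *= 60.0
        mz = inten = None
        for arr in spec.iterfind(".//mzml:binaryDataArray", ns):
            acc = {cv.get("accession") for cv in arr.findall("mzml:cvParam", ns)}
            if "MS:1000514" in acc:
                mz = _decode_binary_array(arr, ns)
            elif "MS:1000515" in acc:
                inten = _decode_binary_array(arr, ns)
        if mz is None or inten is None:
            raise ValidationError(f"{path}: spectrum missing m/z or intensity array")
        if mz_axis is None:
            mz_axis = mz
        if mz.shape != mz_axis.shape or not np.allclose(mz, mz_axis):
            inten = np.interp(mz_axis, mz, inten, left=0.0, right=0.0)
        times.append(t)
        rows.append(inten)
    if mz_axis is None:
        raise ValidationError(f"{path}: no MS1 spectra found")
    return Acquisition(
        sample=sample,
        mz_axis=mz_axis,
        times=np.asarray(times),
        intensities=np.vstack(rows),
    )


# ---------------------------------------------------------- feature matrix

def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    meta = fm.row_meta[list(ROW_META_COLUMNS)].reset_index(drop=True)
    data = pd.DataFrame(fm.X, columns=[_FLOAT_FMT % v for v in fm.bin_mz])
    df = pd.concat([meta, data], axis=1)
    with open(path, "w") as fh:
        fh.write(f"# normalized={str(fm.normalized).lower()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# normalized="):
            raise ValidationError(f"{path}: missing '# normalized=' header")
        normalized = header.split("=", 1)[1] == "true"
        df = pd.read_csv(fh, sep="\t", dtype={c: str for c in ROW_META_COLUMNS})
    bin_cols = [c for c in df.columns if c not in ROW_META_COLUMNS]
    bin_mz = np.asarray([float(c) for c in bin_cols])
    X = df[bin_cols].to_numpy(dtype=float) if bin_cols else np.empty((len(df), 0))
    meta = df[list(ROW_META_COLUMNS)].copy()
    if len(meta):
        meta["fragment_index"] = meta["fragment_index"].astype(int)
    # FeatureMatrix validation enforces the row-sum invariant when normalized.
    return FeatureMatrix(bin_mz=bin_mz, X=X, row_meta=meta, normalized=normalized)


# ------------------------------------------------------------------ config

def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; all keys optional, unknown keys rejected."""
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValidationError(f"config {path} must be a YAML mapping")
            overrides = loaded
    cfg = PipelineConfig().with_overrides(overrides)
    logger.info("resolved pipeline config: %s", cfg)
    return cfg
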
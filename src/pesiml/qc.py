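"""Daily instrument check: mass accuracy and intensity ratios vs a standard.

Emulates the routine start-of-day verification against a polypropylene
glycol (PPG) calibrant mixture: each reference ion must be found within a
mass tolerance and its intensity relative to the base peak must agree
with the reference ratio within a fractional tolerance.

The shipped reference file (``data/ppg_reference_synthetic.json``) is a
synthetic stand-in: the monitored ion list of the vendor check is not
published, so a plausible glycerol-initiated PPG [M+Na]+ oligomer series
is provided as *data*, not hardcoded chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .model import PeakList, ValidationError

__all__ = ["CalibrationReference", "QCReport", "load_reference", "default_reference_path",
           "check_calibration"]


@dataclass(frozen=True)
class CalibrationReference:
    """Expected calibrant peaks: ascending m/z, intensities relative to base peak."""

    expected_mz: np.ndarray
    expected_relative_intensity: np.ndarray
    mass_tol_da: float = 0.5
    ratio_tol_fraction: float = 0.30

    def __post_init__(self) -> None:
        mz = np.asarray(self.expected_mz, dtype=float)
        ri = np.asarray(self.expected_relative_intensity, dtype=float)
        object.__setattr__(self, "expected_mz", mz)
        object.__setattr__(self, "expected_relative_intensity", ri)
        if mz.size == 0 or mz.shape != ri.shape:
            raise ValidationError("reference needs equally sized, non-empty mz/intensity")
        if not np.all(np.diff(mz) > 0):
            raise ValidationError("expected_mz must be strictly ascending")
        if np.any(ri <= 0) or np.any(ri > 1):
            raise ValidationError("relative intensities must lie in (0, 1]")
        if np.count_nonzero(ri == 1.0) != 1:
            raise ValidationError("exactly one reference entry must be the base peak (1.0)")
        if self.mass_tol_da <= 0 or self.ratio_tol_fraction <= 0:
            raise ValidationError("tolerances must be > 0")


@dataclass(frozen=True)
class QCReport:
    """Outcome of one calibration check (a pure function of its inputs)."""

    passed: bool
    matched: tuple[bool, ...]
    mass_errors_da: tuple[float, ...]
    ratio_deviations: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "passed": self.passed,
            "matched": list(self.matched),
            "mass_errors_da": [None if np.isnan(v) else v for v in self.mass_errors_da],
            "ratio_deviations": [None if np.isnan(v) else v for v in self.ratio_deviations],
        }


def default_reference_path() -> Path:
    return Path(str(resources.files("pesiml").joinpath("data/ppg_reference_synthetic.json")))


def load_reference(path: str | Path | None = None) -> CalibrationReference:
    path = Path(path) if path is not None else default_reference_path()
    with open(path) as fh:
        obj = json.load(fh)
    peaks = obj["peaks"]
    return CalibrationReference(
        expected_mz=np.asarray([p["mz"] for p in peaks], dtype=float),
        expected_relative_intensity=np.asarray(
            [p["relative_intensity"] for p in peaks], dtype=float
        ),
        mass_tol_da=float(obj.get("mass_tol_da", 0.5)),
        ratio_tol_fraction=float(obj.get("ratio_tol_fraction", 0.30)),
    )


def check_calibration(peaklist: PeakList, reference: CalibrationReference) -> QCReport:
    """Match each reference ion to its nearest observed peak and verify.

    Matching is deterministic: nearest observed peak within ``mass_tol_da``,
    distance ties broken toward lower m/z.  The check passes iff every
    reference ion is matched, every |mass error| <= ``mass_tol_da`` and
    every relative-intensity deviation <= ``ratio_tol_fraction``.
    """
    if len(peaklist) == 0:
        raise ValidationError("check_calibration needs a non-empty peak list")
    obs_mz, obs_int = peaklist.mz, peaklist.intensity
    base_idx = int(np.flatnonzero(reference.expected_relative_intensity == 1.0)[0])

    def nearest(target: float) -> int:
        d = np.abs(obs_mz - target)
        best = float(d.min())
        # ties toward lower m/z: first index attaining the minimum
        return int(np.flatnonzero(d <= best + 1e-12)[0])

    matched, mass_err, obs_rel_int = [], [], []
    for mz in reference.expected_mz:
        i = nearest(float(mz))
        err = float(obs_mz[i] - mz)
        ok = abs(err) <= reference.mass_tol_da
        matched.append(ok)
        mass_err.append(err if ok else float("nan"))
        obs_rel_int.append(float(obs_int[i]) if ok else float("nan"))

    ratio_dev = [float("nan")] * len(matched)
    if matched[base_idx]:
        base_obs = obs_rel_int[base_idx]
        for k, (ok, oi) in enumerate(zip(matched, obs_rel_int)):
            if ok and base_obs > 0:
                expected = float(reference.expected_relative_intensity[k])
                ratio_dev[k] = abs(oi / base_obs - expected) / expected
    passed = (
        all(matched)
        and all(not np.isnan(v) and v <= reference.ratio_tol_fraction for v in ratio_dev)
    )
    return QCReport(
        passed=bool(passed),
        matched=tuple(matched),
        mass_errors_da=tuple(mass_err),
        ratio_deviations=tuple(ratio_dev),
    )
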
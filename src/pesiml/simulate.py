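"""Synthetic PESI-MS cohort generator.

The study's raw spectra are not publicly deposited, so this module
generates cohorts with the statistical structure the downstream analysis
assumes: class-dependent peak profiles, a per-patient multiplicative
random effect shared by paired tumour / non-tumour samples, per-scan
multiplicative noise, an additive noise floor, and an end-of-run signal
decay (needle contamination) that motivates discarding the last two
10-second fragments of each 2-minute acquisition.

Generative model
----------------
The expected apex intensity of peak *j* in a scan at time *t* for a sample
of tissue class *c* from patient *p* is::

    A_j(t) = exp(b_j + e_{c,j} + u_p) * d(t) * eps

with ``b_j`` the peak's base log-intensity, ``e_{c,j}`` its class
log-fold effect, ``u_p ~ N(0, patient_sd^2)`` the patient effect,
``eps ~ LogNormal(0, scan_sd^2)`` drawn independently per peak per scan,
and ``d(t) = 1`` for ``t < t0_s``, ``exp(-(t - t0_s)/tau_s)`` afterwards.
Peaks are rendered as Gaussians (sd ``peak_width_sigma``) on the m/z grid
and a Gaussian noise floor (sd ``additive_noise_sd``) is added, with the
total clipped at zero.

Intensities are multiplicative and positive (log-normal effects)
because electrospray ion currents are heteroscedastic; the patient
effect scales all peaks jointly, so TIC normalization largely removes
it — which is exactly why the real protocol normalizes on the TIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterator, Mapping

import numpy as np

from .model import Acquisition, SampleRecord, ValidationError

__all__ = ["PeakTemplate", "SimConfig", "make_peak_library", "simulate_acquisition",
           "simulate_cohort", "iter_cohort"]

#: The three class contrasts that receive disjoint discriminative peak sets.
CONTRASTS = ("hcc_vs_nt", "mfccc_vs_nt", "hcc_vs_mfccc")


@dataclass(frozen=True)
class PeakTemplate:
    """One spectral peak of the synthetic library."""

    mz: float
    base_log_intensity: float
    class_effects: Mapping[str, float]  # tissue label -> log-fold effect
    peak_width_sigma: float

    def __post_init__(self) -> None:
        if not 10.0 <= self.mz <= 2000.0:
            raise ValidationError(f"peak mz {self.mz} outside [10, 2000]")
        if self.peak_width_sigma <= 0:
            raise ValidationError("peak_width_sigma must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults reproduce the published study design: 117 HCC patients of
    whom 105 contribute a paired non-tumour sample, and 50 MFCCC patients
    of whom 46 do (318 samples in total), each analysed for 120 s at one
    scan per second over m/z 10-2000 on a 0.1 Da grid.
    """

    n_patients_hcc: int = 117
    n_patients_mfccc: int = 50
    paired_fraction_hcc: float = 105 / 117
    paired_fraction_mfccc: float = 46 / 50
    n_background_peaks: int = 60
    n_discriminative_peaks: int = 8  # per contrast
    delta: float = 2.0  # log-fold class effect of discriminative peaks
    patient_sd: float = 0.30
    scan_sd: float = 0.15
    additive_noise_sd: float = 5.0
    t0_s: float = 100.0
    tau_s: float = 10.0
    scans_per_second: float = 1.0
    duration_s: float = 120.0
    mz_min: float = 10.0
    mz_max: float = 2000.0
    grid_da: float = 0.1
    peak_mz_lo: float = 50.0
    peak_mz_hi: float = 1500.0
    min_peak_spacing_da: float = 3.0
    peak_width_sigma: float = 0.15
    base_log_intensity_lo: float = math.log(1e3)
    base_log_intensity_hi: float = math.log(3e4)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.patient_sd, self.scan_sd, self.additive_noise_sd) < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0.0 <= self.t0_s <= 120.0:
            raise ValidationError("t0_s must lie in [0, 120] s")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if self.tau_s <= 0:
            raise ValidationError("tau_s must be > 0")
        for frac in (self.paired_fraction_hcc, self.paired_fraction_mfccc):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("paired fractions must lie in [0, 1]")

    def with_overrides(self, **overrides) -> "SimConfig":
        unknown = sorted(set(overrides) - {f.name for f in fields(self)})
        if unknown:
            raise ValidationError(f"unknown SimConfig keys {unknown}")
        return replace(self, **overrides)

    @property
    def mz_axis(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.grid_da)) + 1
        return self.mz_min + self.grid_da * np.arange(n)


def make_peak_library(cfg: SimConfig) -> list[PeakTemplate]:
    """Draw the cohort-wide peak library, deterministic under ``cfg.seed``.

    Discriminative peaks for the three contrasts are disjoint sets.
    ``hcc_vs_nt`` peaks shift HCC intensities by +/- ``delta`` log units,
    ``mfccc_vs_nt`` peaks shift MFCCC, and ``hcc_vs_mfccc`` peaks shift
    HCC and MFCCC in opposite directions (both by ``delta``), leaving
    non-tumour tissue untouched in every case.
    """
    n_total = cfg.n_background_peaks + 3 * cfg.n_discriminative_peaks
    slots = np.arange(cfg.peak_mz_lo, cfg.peak_mz_hi, cfg.min_peak_spacing_da)
    if n_total > slots.size:
        raise ValidationError(
            f"{n_total} peaks requested but the m/z range hosts at most "
            f"{slots.size} at spacing {cfg.min_peak_spacing_da} Da"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    chosen = np.sort(rng.choice(slots, size=n_total, replace=False))
    # jitter keeps inter-peak gaps >= min_peak_spacing_da / 3
    chosen = chosen + rng.uniform(
        -cfg.min_peak_spacing_da / 3, cfg.min_peak_spacing_da / 3, size=n_total
    )
    base = rng.uniform(cfg.base_log_intensity_lo, cfg.base_log_intensity_hi, size=n_total)
    roles = (
        ["background"] * cfg.n_background_peaks
        + [c for c in CONTRASTS for _ in range(cfg.n_discriminative_peaks)]
    )
    rng.shuffle(roles)
    library = []
    for mz, b, role in zip(chosen, base, roles):
        effects = {"HCC": 0.0, "MFCCC": 0.0, "NONTUMOUR": 0.0}
        if role != "background":
            sign = float(rng.choice([-1.0, 1.0]))
            if role == "hcc_vs_nt":
                effects["HCC"] = sign * cfg.delta
            elif role == "mfccc_vs_nt":
                effects["MFCCC"] = sign * cfg.delta
            else:  # hcc_vs_mfccc
                effects["HCC"] = sign * cfg.delta
                effects["MFCCC"] = -sign * cfg.delta
        library.append(
            PeakTemplate(
                mz=float(mz),
                base_log_intensity=float(b),
                class_effects=effects,
                peak_width_sigma=cfg.peak_width_sigma,
            )
        )
    return library


def _decay(times: np.ndarray, cfg: SimConfig) -> np.ndarray:
    d = np.ones_like(times)
    late = times >= cfg.t0_s
    d[late] = np.exp(-(times[late] - cfg.t0_s) / cfg.tau_s)
    return d


def simulate_acquisition(
    library: list[PeakTemplate],
    sample: SampleRecord,
    cfg: SimConfig,
    patient_effect: float,
    rng: np.random.Generator,
) -> Acquisition:
    """Render one 2-minute acquisition for ``sample`` on the m/z grid."""
    axis = cfg.mz_axis
    n_scans = int(round(cfg.duration_s * cfg.scans_per_second))
    times = np.arange(n_scans) / cfg.scans_per_second
    decay = _decay(times, cfg)

    mzs = np.array([p.mz for p in library])
    sigmas = np.array([p.peak_width_sigma for p in library])
    log_amp = np.array(
        [p.base_log_intensity + p.class_effects[sample.tissue_label] for p in library]
    ) + patient_effect

    # per-(scan, peak) multiplicative log-normal noise
    if cfg.scan_sd > 0:
        eps = np.exp(rng.normal(0.0, cfg.scan_sd, size=(n_scans, len(library))))
    else:
        eps = np.ones((n_scans, len(library)))
    amps = np.exp(log_amp)[None, :] * decay[:, None] * eps

    intensities = np.zeros((n_scans, axis.size))
    # each peak only touches grid points within +/- 6 sigma of its centre
    for j, (mz, sig) in enumerate(zip(mzs, sigmas)):
        lo = np.searchsorted(axis, mz - 6 * sig)
        hi = np.searchsorted(axis, mz + 6 * sig)
        shape = np.exp(-0.5 * ((axis[lo:hi] - mz) / sig) ** 2)
        intensities[:, lo:hi] += amps[:, j][:, None] * shape[None, :]

    if cfg.additive_noise_sd > 0:
        intensities += rng.normal(0.0, cfg.additive_noise_sd, size=intensities.shape)
        np.clip(intensities, 0.0, None, out=intensities)

    return Acquisition(sample=sample, mz_axis=axis, times=times, intensities=intensities)


def _build_manifest(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[SampleRecord], dict[str, float]]:
    """Sample records plus per-patient random effects (paired samples share one)."""
    records: list[SampleRecord] = []
    patient_effects: dict[str, float] = {}
    arms = (
        ("H", "HCC", "HCC_cohort", cfg.n_patients_hcc, cfg.paired_fraction_hcc),
        ("M", "MFCCC", "MFCCC_cohort", cfg.n_patients_mfccc, cfg.paired_fraction_mfccc),
    )
    for prefix, tumour_label, cohort, n_patients, paired_frac in arms:
        n_paired = int(round(paired_frac * n_patients))
        paired = set(rng.choice(n_patients, size=n_paired, replace=False).tolist())
        for i in range(n_patients):
            pid = f"{prefix}{i + 1:03d}"
            patient_effects[pid] = float(rng.normal(0.0, cfg.patient_sd))
            records.append(SampleRecord(f"{pid}T", pid, tumour_label, cohort))
            if i in paired:
                records.append(SampleRecord(f"{pid}N", pid, "NONTUMOUR", cohort))
    return records, patient_effects


def iter_cohort(cfg: SimConfig) -> Iterator[Acquisition]:
    """Lazily yield one acquisition per manifest sample (memory-bounded).

    Deterministic under ``cfg.seed``: each sample draws from its own
    child RNG stream, so the cohort is reproducible regardless of how
    the iterator is consumed.
    """
    manifest, effects = simulate_manifest(cfg)
    library = make_peak_library(cfg)
    for idx, rec in enumerate(manifest):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, idx]))
        yield simulate_acquisition(library, rec, cfg, effects[rec.patient_id], rng)


def simulate_manifest(cfg: SimConfig) -> tuple[list[SampleRecord], dict[str, float]]:
    """Manifest and patient random effects, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    return _build_manifest(cfg, rng)


def simulate_cohort(cfg: SimConfig) -> tuple[list[SampleRecord], list[Acquisition]]:
    """Materialize the whole cohort in memory (use :func:`iter_cohort` at scale)."""
    manifest, _ = simulate_manifest(cfg)
    return manifest, list(iter_cohort(cfg))
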
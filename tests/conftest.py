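import numpy as np
import pandas as pd
import pytest

from pesiml.model import FeatureMatrix
from pesiml.simulate import SimConfig


@pytest.fixture(scope="session")
def fast_sim() -> SimConfig:
    """Small, quick cohort: narrow m/z range, sparse scans, full pairing."""
    return SimConfig(
        n_patients_hcc=4,
        n_patients_mfccc=3,
        paired_fraction_hcc=1.0,
        paired_fraction_mfccc=1.0,
        n_background_peaks=20,
        n_discriminative_peaks=4,
        mz_max=300.0,
        peak_mz_lo=50.0,
        peak_mz_hi=280.0,
        scans_per_second=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def fast_cohort(fast_sim):
    from pesiml.preprocess import preprocess_cohort
    from pesiml.simulate import iter_cohort, simulate_manifest

    manifest, _ = simulate_manifest(fast_sim)
    fm = preprocess_cohort(iter_cohort(fast_sim))
    return manifest, fm


def random_feature_matrix(rng: np.random.Generator, n_rows: int = 6, n_bins: int = 4,
                          normalized: bool = False) -> FeatureMatrix:
    X = rng.uniform(0.1, 5.0, size=(n_rows, n_bins))
    if normalized:
        X = X / X.sum(axis=1, keepdims=True)
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i // 2}" for i in range(n_rows)],
            "patient_id": [f"P{i // 2}" for i in range(n_rows)],
            "fragment_index": [i % 2 for i in range(n_rows)],
            "tissue_label": ["HCC" if i % 2 else "NONTUMOUR" for i in range(n_rows)],
            "cohort": "HCC_cohort",
        }
    )
    return FeatureMatrix(
        bin_mz=np.sort(rng.uniform(50, 900, n_bins)),
        X=X,
        row_meta=meta,
        normalized=normalized,
    )


def single_linkage_bins(mz: np.ndarray, tol: float) -> list[set[int]]:
    """Brute-force oracle: single-linkage clustering of 1-D points cut at tol."""
    from scipy.cluster.hierarchy import fcluster, linkage

    if mz.size == 1:
        return [{0}]
    Z = linkage(mz[:, None], method="single")
    labels = fcluster(Z, t=tol, criterion="distance")
    out: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(i)
    return sorted(out.values(), key=lambda s: float(np.min(mz[list(s)])))
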
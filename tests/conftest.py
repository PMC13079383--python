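import numpy as np
import pandas as pd
import pytest

from aupheno import catalog, features, ingest, simulate


def tiny_cohort_config(seed=3, **kw):
    """Small, fast cohort sharing the study's structure."""
    defaults = dict(
        n_case=12,
        n_control=10,
        fps=15.0,
        duration_mean_s=8.0,
        duration_jitter_s=1.0,
        seed=seed,
    )
    defaults.update(kw)
    return simulate.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate.generate_cohort(tiny_cohort_config())


def cohort_to_matrix(cohort, frame_threshold=0.80, participant_threshold=0.90):
    filtered, entries = [], []
    for p in cohort:
        f, e = ingest.filter_low_confidence(p.sequence, frame_threshold)
        filtered.append(f)
        entries.append(e)
    qc = ingest.assess_validity(entries, participant_threshold)
    matrix = features.build_feature_matrix(filtered, qc, {p.id: p.group for p in cohort})
    return matrix, qc


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    matrix, _ = cohort_to_matrix(small_cohort)
    return matrix


@pytest.fixture(scope="session")
def small_clinical(small_cohort):
    return simulate.clinical_frame(small_cohort)


def make_sequence(pid="P1", n=10, confidence=None, success=None, seed=0, presence=None,
                  intensity=None):
    """Hand-built AUSequence with controllable channels (same value for
    every AU unless per-AU overrides are given)."""
    rng = np.random.default_rng(seed)
    data = {
        "frame": np.arange(1, n + 1),
        "face_id": np.zeros(n, dtype=int),
        "timestamp": np.arange(n) / 30.0,
        "confidence": np.ones(n) if confidence is None else np.asarray(confidence, float),
        "success": np.ones(n, dtype=int) if success is None else np.asarray(success, int),
        "pose_Rx": rng.normal(0, 0.01, n),
        "pose_Ry": rng.normal(0, 0.01, n),
        "pose_Rz": rng.normal(0, 0.01, n),
    }
    for au in catalog.INTENSITY_AU_IDS:
        data[catalog.intensity_column(au)] = (
            rng.uniform(0, 5, n) if intensity is None else np.asarray(intensity, float)
        )
    for au in catalog.AU_IDS:
        data[catalog.presence_column(au)] = (
            rng.integers(0, 2, n) if presence is None else np.asarray(presence, int)
        )
    df = pd.DataFrame(data, columns=ingest.openface_columns())
    return ingest.AUSequence(participant_id=pid, frames=df, n_raw=n)


def gaussian_matrix(n_case, n_control, p, seed, effect=None):
    """Plain Gaussian feature matrix (no AU structure) for classifier tests.

    ``effect`` maps column index -> additive shift applied to cases.
    """
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    X = rng.normal(size=(n, p))
    if effect:
        for j, d in effect.items():
            X[:n_case, j] += d
    ids = [f"P{i:03d}" for i in range(n)]
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=ids)
    return features.FeatureMatrix(
        X=pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=[f"f{j}" for j in range(p)]),
        labels=labels,
    )
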
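import numpy as np
import pytest

from nosomap.classify import FOUR_CLASS, lda_fit
from nosomap.features import sffs_select
from nosomap.processing import process_many
from nosomap.synth import build_class_profiles, simulate_sv_dataset


@pytest.fixture(scope="session")
def profiles():
    return build_class_profiles()


@pytest.fixture(scope="session")
def sv_training():
    """Small processed SV training set shared across the suite."""
    ds = simulate_sv_dataset(
        {c: 12 for c in ("mm", "gb", "me", "lgg", "no")}, seed=42
    )
    X, canon, _ = process_many(ds.fids)
    y = np.array([FOUR_CLASS.map_label(lbl) for lbl in ds.labels])
    return X, canon, y


@pytest.fixture(scope="session")
def trained_model(sv_training):
    """LDA on a small SFFS feature set (shared, deterministic)."""
    X, _, y = sv_training
    fset = sffs_select(X, y, 4, seed=0)
    idx = list(fset.indices)
    model = lda_fit(X[:, idx], y, feature_indices=tuple(idx))
    return model, fset
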
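import numpy as np
import pytest

import sfcoupling as sfc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Reduced synthetic study: small parcellation and cohort so the full
    pipeline runs in seconds while keeping every structural feature."""
    return sfc.SimConfig(
        n_adhd=14, n_control=14, n_nodes=48, retention=0.8,
        density=0.35, seed=71,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return sfc.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    kept, _ = sfc.qc_filter(small_study.records)
    keys = {r.scan_key for r in kept}
    scans = [t for t in small_study.scans if t[0].scan_key in keys]
    cfg = sfc.RunConfig(n_nodes=small_study.config.n_nodes, analysis="both")
    return sfc.analyze_scans(scans, cfg)


def make_symmetric(n, rng, nonneg=True):
    w = rng.random((n, n)) * (10.0 if nonneg else 1.0)
    w = (w + w.T) / 2
    if not nonneg:
        w = w * 2 - w.mean()
        w = np.clip((w + w.T) / 2, -1, 1)
    np.fill_diagonal(w, 0.0)
    return w
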
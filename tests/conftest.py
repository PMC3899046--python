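"""Shared fixtures: cached scaling ensembles for the heavier statistics."""

import pytest

import fiberwalk as fw


@pytest.fixture(scope="session")
def scaling_ensembles():
    """Lazily computed, session-cached scaling ensembles keyed by (dim, mode).

    300 walks of length 200 with backtrack restarts: the reduced protocol
    for exponent estimates shared by the MSD, contraction and transient
    checks.
    """
    cache = {}

    def get(dimension: int, mode: str) -> fw.experiments.ScalingEnsemble:
        key = (dimension, mode)
        if key not in cache:
            cfg = fw.EnsembleConfig(dimension=dimension, mode=mode,
                                    n_walks=300, max_steps=200, seed=0,
                                    restart_policy="backtrack", min_length=200)
            cache[key] = fw.scaling_ensemble(cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def stopping_10k():
    """Session-cached stopping-time ensembles (n=10,000, 2D, both modes)."""
    out = {}
    for mode in ("growing_saw", "fiber_walk"):
        cfg = fw.EnsembleConfig(dimension=2, mode=mode, n_walks=10_000,
                                max_steps=300, seed=0)
        out[mode] = fw.stopping_time_ensemble(cfg)
    return out
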
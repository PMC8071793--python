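import numpy as np
import pytest

import forcemode as fm


@pytest.fixture(scope="session")
def default_ensemble():
    """The calibrated synthetic ensemble at seed 1 (study-shaped: 7
    transitioning + 3 control replicas, 500 frames, 521 features)."""
    return fm.generate_force_ensemble(fm.SyntheticEnsembleSpec(seed=1))


@pytest.fixture(scope="session")
def default_cv(default_ensemble):
    """Leave-one-replica-out cross-validation of the seed-1 ensemble
    under the default component-selection policy."""
    return fm.cross_validate(default_ensemble.replicas(), "auto")


@pytest.fixture(scope="session")
def multi_seed_metrics():
    """Recovery/validation metrics of the default ensemble across
    generator seeds 1-10 (computed once; ensembles are discarded)."""
    metrics = []
    for seed in range(1, 11):
        ens = fm.generate_force_ensemble(fm.SyntheticEnsembleSpec(seed=seed))
        report = fm.cross_validate(ens.replicas(), "auto")
        tc = ens.true_coefficients
        ev = report.ensemble_vector
        metrics.append({
            "seed": seed,
            "cosine": float(ev @ tc
                            / (np.linalg.norm(ev) * np.linalg.norm(tc))),
            "min_auc": report.min_transition_auc(),
            "min_r": report.min_transition_pearson(),
        })
    return metrics


@pytest.fixture()
def small_system():
    return fm.generate_toy_system(5, 6, 3, seed=11)
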
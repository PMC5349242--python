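import numpy as np
import pytest

from ishprofiler import (
    SyntheticSpec,
    featurize_patches,
    make_training_patches,
    render_core,
    train_classifier,
)

# compact but highly accurate grid for the shared model; the full default
# grid is exercised separately by the classifier CV test
FAST_C_GRID = (1.0, 8.0)
FAST_GAMMA_GRID = (0.125, 1.0)


@pytest.fixture(scope="session")
def training_patches():
    """1,000 labelled synthetic patches, 200 per class."""
    spec = SyntheticSpec(seed=7, noise_sd=5)
    return make_training_patches(spec, 200)


@pytest.fixture(scope="session")
def model(training_patches):
    patches, labels = training_patches
    return train_classifier(featurize_patches(patches), labels,
                            c_grid=FAST_C_GRID, gamma_grid=FAST_GAMMA_GRID,
                            seed=0)


@pytest.fixture(scope="session")
def small_core():
    """A 512 px core with a known mix of planted signals."""
    spec = SyntheticSpec(image_side=512, n_nuclei=8, n_pten=15, n_cep10=30,
                        n_mixed=5, noise_sd=5, seed=11)
    return render_core(spec)


def match_detections(truth_xy, det_xy, tol=2.0):
    """Greedy nearest one-to-one matching; returns (tp, recall, precision)."""
    from scipy.spatial import cKDTree

    truth_xy = np.asarray(truth_xy, float)
    det_xy = np.asarray(det_xy, float)
    if len(det_xy) == 0 or len(truth_xy) == 0:
        return 0, 0.0, 0.0
    dist, idx = cKDTree(truth_xy).query(det_xy)
    matched = set()
    tp = 0
    for i in np.argsort(dist):
        if dist[i] <= tol and idx[i] not in matched:
            matched.add(int(idx[i]))
            tp += 1
    return tp, tp / len(truth_xy), tp / len(det_xy)
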
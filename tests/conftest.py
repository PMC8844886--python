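import numpy as np
import pytest
from hypothesis import settings

from ribofish.simulate import FishStackParams, default_whitelist, gen_fish_stack

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def whitelist():
    return default_whitelist()


@pytest.fixture(scope="session")
def small_stack():
    """One modest two-channel stack with truth, shared across image tests."""
    params = FishStackParams(
        shape=(12, 96, 128), n_puncta=30, frac_inside=0.5, seed=0
    )
    field, truth = gen_fish_stack(params)
    return field, truth


def greedy_match_f1(detected_vox: np.ndarray, true_vox: np.ndarray, radius: float = 2.0):
    """Greedy nearest-pair matching between detections and planted truth.

    Pairs are matched closest-first (voxel-unit Euclidean distance, one
    match per spot, cutoff ``radius``); returns (f1, precision, recall).
    """
    if len(detected_vox) == 0 or len(true_vox) == 0:
        return 0.0, 0.0, 0.0
    from scipy.spatial.distance import cdist

    D = cdist(detected_vox, true_vox)
    used_d, used_t = set(), set()
    tp = 0
    for d, i, j in sorted(
        (D[i, j], i, j) for i in range(D.shape[0]) for j in range(D.shape[1])
    ):
        if d > radius:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    precision = tp / len(detected_vox)
    recall = tp / len(true_vox)
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return f1, precision, recall
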
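import numpy as np
import pytest

import hdpseg as H


def tv_distance(empirical_counts: dict, exact: dict) -> float:
    """Total-variation distance between an empirical histogram and exact probs."""
    tot = sum(empirical_counts.values())
    keys = set(empirical_counts) | set(exact)
    return 0.5 * sum(
        abs(empirical_counts.get(k, 0) / tot - exact.get(k, 0.0)) for k in keys
    )


def sample_partition_histogram(images, hp, mode, n_sweeps, burn, seed):
    """Run the sampler, returning counts of canonical configuration keys."""
    from collections import Counter

    state = H.FranchiseState(images, hp, mode)
    sweep = H.gibbs_sweep_single if mode == "single_dp" else H.gibbs_sweep_joint
    key = state.partition_key if mode == "single_dp" else state.franchise_key
    sweep(state, hp, rng=seed)
    counts = Counter()
    for s in range(burn + n_sweeps):
        sweep(state, hp)
        if s >= burn:
            counts[key()] += 1
    state.check_consistency()
    return counts


@pytest.fixture(scope="session")
def two_block_image():
    """2x2 image with two clearly separated intensity pairs."""
    return np.array([[-1.0, -1.0], [1.0, 1.0]])


@pytest.fixture(scope="session")
def joint_pair():
    """Two 1x2 images with moderately separated values."""
    return [np.array([[-1.0, 1.0]]), np.array([[-0.8, 1.2]])]
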
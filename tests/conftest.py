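import numpy as np
import pytest
from hypothesis import settings

from emdock import analyze_half_maps, AtomModel, OversamplingInfo
from emdock.synthetic import (SyntheticSpec, generate_true_map,
                              simulate_half_maps)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


def align_ground_truth(gt, terms):
    """Index array mapping analysis terms onto ground-truth terms."""
    key = {tuple(h): i for i, h in enumerate(gt.terms.hkl)}
    return np.array([key[tuple(h)] for h in terms.hkl])


def shell_chunks(s, bins):
    order = np.argsort(s, kind="stable")
    return np.array_split(order, bins)


@pytest.fixture(scope="session")
def small_experiment():
    """Fast 48^3 fixture for unit tests: maps, ground truth, analysis."""
    spec = SyntheticSpec(n_grid=48, n_atoms=150, cluster_radius=14.0,
                         seed=1)
    true_map, gt = generate_true_map(spec)
    m1, m2, gt = simulate_half_maps(true_map, gt)
    analysis = analyze_half_maps(m1, m2, d_min=spec.d_min)
    return {"spec": spec, "true_map": true_map, "gt": gt, "m1": m1,
            "m2": m2, "analysis": analysis}


@pytest.fixture(scope="session")
def default_experiment():
    """The default 64^3 study fixture (used by the recovery criteria)."""
    spec = SyntheticSpec(seed=1)
    true_map, gt = generate_true_map(spec)
    m1, m2, gt = simulate_half_maps(true_map, gt)
    analysis = analyze_half_maps(m1, m2, d_min=spec.d_min)
    return {"spec": spec, "true_map": true_map, "gt": gt, "m1": m1,
            "m2": m2, "analysis": analysis}


@pytest.fixture(scope="session")
def small_docking(small_experiment):
    """Model/oversampling companions to the small fixture."""
    spec = small_experiment["spec"]
    gt = small_experiment["gt"]
    model = AtomModel(gt.coords, width=spec.atom_width)
    box_volume = small_experiment["m1"].box_volume
    over = OversamplingInfo(4.0 / 3.0 * np.pi * spec.cluster_radius ** 3,
                            box_volume)
    return {"model": model, "over": over,
            "norm": small_experiment["analysis"].normalized}
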
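import numpy as np
import pytest

from nucleoscore import synthetic


@pytest.fixture(scope="session")
def normal_field():
    """One deterministic normal-phenotype field with ground truth."""
    return synthetic.generate_field(synthetic.PhenotypeParams(phenotype="normal", seed=7))


@pytest.fixture(scope="session")
def noiseless_normal_field():
    params = synthetic.PhenotypeParams(
        phenotype="normal", seed=11, poisson_scale=0.0, gauss_sigma=0.0
    )
    return synthetic.generate_field(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def per_object_iou(segmented, truth):
    """Best-match IoU for every ground-truth object."""
    ious = []
    for label in range(1, truth.n_objects + 1):
        gt = truth.labels == label
        best = 0.0
        candidates = np.unique(segmented.labels[gt])
        for cand in candidates[candidates > 0]:
            seg = segmented.labels == cand
            best = max(best, (gt & seg).sum() / (gt | seg).sum())
        ious.append(best)
    return ious


def union_iou_per_nucleus(segmented, truth, nuclei_truth):
    """IoU of the unions of nucleolus pixels, nucleus by nucleus."""
    ious = []
    for nucleus_label in range(1, nuclei_truth.n_objects + 1):
        inside = nuclei_truth.labels == nucleus_label
        gt = (truth.labels > 0) & inside
        seg = (segmented.labels > 0) & inside
        union = (gt | seg).sum()
        if union == 0:
            continue
        ious.append((gt & seg).sum() / union)
    return ious
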
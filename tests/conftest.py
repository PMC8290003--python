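import numpy as np
import pytest

import ntquant as nq


@pytest.fixture(scope="session")
def noise_free_config():
    return nq.ImageSimConfig(
        n_cells=40,
        nt_fraction=0.1,
        gaussian_noise_sd=0.0,
        poisson_noise=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_sample(noise_free_config):
    return nq.simulate_sample(noise_free_config)


@pytest.fixture(scope="session")
def measured_noise_free(noise_free_sample):
    """Full segment->regions->measure run on a noise-free sample."""
    image, truth = noise_free_sample
    nuclei = nq.segment_nuclei(image)
    masks = nq.define_cell_regions(nuclei, image)
    records = nq.measure_cells(masks, image)
    return image, truth, masks, records


def match_measured_to_truth(masks, records, truth):
    """Map each measured cell to its nearest ground-truth cell by centroid."""
    from scipy import ndimage as ndi

    ids = masks.cell_ids
    centroids = ndi.center_of_mass(
        np.ones_like(masks.nuclear_labels), masks.nuclear_labels, ids
    )
    by_id = dict(zip(ids, centroids))
    pairs = []
    for rec in records:
        cy, cx = by_id[rec.cell_id]
        d = np.hypot(truth.center_row_px - cy, truth.center_col_px - cx)
        pairs.append((rec, truth.loc[d.idxmin()], float(d.min())))
    return pairs
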
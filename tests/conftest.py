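import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, build_matrix, records_to_alignment
from barcodekit.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """6 species x 4 specimens, clear barcode gap, no pseudogenes."""
    cfg = SimConfig(n_species=6, seqs_per_species=4, intra_div=0.01, inter_div=0.08, seed=11)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_coi_matrix(small_dataset):
    _, records, _ = small_dataset
    return build_matrix(records_to_alignment(records["COI"], "COI"), "JC69")


def truth_partition(truth) -> frozenset:
    groups = {}
    for sid, sp in zip(truth["specimen_id"], truth["species_index"]):
        groups.setdefault(sp, set()).add(sid)
    return frozenset(frozenset(g) for g in groups.values())


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    raw = rng.uniform(0, 0.5, size=(n, n))
    data = np.triu(raw, k=1)
    data = data + data.T
    return DistanceMatrix([f"t{i}" for i in range(n)], data, "p")
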
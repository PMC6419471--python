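"""Shared fixtures: crafted distance matrices and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from motu_concord.datasets import Dataset, SpecimenRecord
from motu_concord.distances import DistanceMatrix, distance_matrix
from motu_concord.simulate import SimConfig, simulate_dataset

# canonical planted-gap study conditions: 20 species x 5 specimens,
# within-species K2P 1%, between-species 10%
GAPPED_CONFIG = dict(
    n_species=20,
    specimens_per_species=5,
    target_intra=0.01,
    target_inter=0.10,
)
FIXTURE_SEED = 1


def dm_from_array(ids: list[str], d: np.ndarray, sites: int = 600) -> DistanceMatrix:
    """Wrap a crafted symmetric distance array as a DistanceMatrix.

    Per-pair site counts are constant and mismatch counts are derived
    from the distances, so p-distances approximate the K2P values.
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    assert d.shape == (n, n)
    sites_m = np.full((n, n), sites, dtype=np.int64)
    diffs = np.rint(np.nan_to_num(d, nan=0.0) * sites).astype(np.int64)
    return DistanceMatrix(list(ids), d, sites_m, diffs)


def block_matrix(group_sizes: list[int], within: float, between: float) -> np.ndarray:
    """Distance array with constant within-group and between-group values."""
    n = sum(group_sizes)
    d = np.full((n, n), between)
    start = 0
    for size in group_sizes:
        d[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(d, 0.0)
    return d


def make_dataset(
    ids: list[str],
    species: list[str],
    genus: list[str] | None = None,
    sequences: list[str] | None = None,
    seq_length: int = 600,
) -> Dataset:
    """Minimal dataset with dummy (or given) equal-length sequences."""
    if sequences is None:
        sequences = ["A" * seq_length] * len(ids)
    if genus is None:
        genus = [sp.split()[0] if sp else "" for sp in species]
    records = [
        SpecimenRecord(specimen_id=i, sequence=s, species=sp, genus=g)
        for i, s, sp, g in zip(ids, sequences, species, genus)
    ]
    return Dataset(records)


@pytest.fixture(scope="session")
def gapped_sim():
    """Simulated dataset with a clean planted barcode gap + its truth."""
    ds, truth, table = simulate_dataset(SimConfig(seed=FIXTURE_SEED, **GAPPED_CONFIG))
    return ds, truth, table


@pytest.fixture(scope="session")
def gapped_dm(gapped_sim):
    ds, _, _ = gapped_sim
    return distance_matrix(ds)


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Random symmetric nonnegative matrix with zero diagonal."""
    a = rng.uniform(0.0, 0.3, size=(n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return dm_from_array([f"t{i}" for i in range(n)], d)
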
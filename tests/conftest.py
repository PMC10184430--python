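import numpy as np
import pytest

import boapred as bp


@pytest.fixture(scope="session")
def small_dataset() -> bp.SyntheticDataset:
    """A small but complete population: 3 breeds, crossbred cohorts, truth."""
    cfg = bp.SimConfig(
        n_markers=200, n_qtl=60, n_purebred_per_breed=80, seed=42
    )
    return bp.simulate(cfg)


@pytest.fixture(scope="session")
def small_partials(small_dataset):
    """Partial genotypes for the small population, all-animal frequencies."""
    ds = small_dataset
    idx = np.arange(ds.genotypes.n_animals)
    freqs = bp.breed_allele_freqs(ds.genotypes, ds.origins, idx)
    return bp.build_partial_genotypes(ds.genotypes, ds.origins, freqs)


def animal_indices(ds: bp.SyntheticDataset, **filters) -> np.ndarray:
    """Positional indices of pedigree rows matching the given column values."""
    ped = ds.pedigree
    sel = np.ones(len(ped), dtype=bool)
    for col, val in filters.items():
        sel &= (ped[col] == val).to_numpy()
    pos = {a: i for i, a in enumerate(ds.genotypes.animal_ids)}
    return np.array([pos[a] for a in ped.loc[sel, "animal"]])
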
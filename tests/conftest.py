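import numpy as np
import pytest

import divmap as dm


def tiny_table(genos, loci=("L1", "L2"), status=None, coords=None):
    """Build a small GenotypeTable from a list of per-sample genotype tuples."""
    n = len(genos)
    status = status or ["in_situ"] * n
    coords = coords or [(-79.0 + 0.01 * i, -4.0) for i in range(n)]
    samples = [
        dm.GeoSample(
            sample_id=f"S{i}",
            lon=coords[i][0],
            lat=coords[i][1],
            status=status[i],
            genotype=tuple(genos[i]),
        )
        for i in range(n)
    ]
    return dm.GenotypeTable(samples, loci)


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic landscape at full study scale (complete data)."""
    cfg = dm.LandscapeConfig(seed=17)
    table, truth = dm.simulate_landscape(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def assignment(landscape):
    _, table, _ = landscape
    grid = dm.make_grid(
        (table.lon.min(), table.lat.min(), table.lon.max() + 1e-9, table.lat.max() + 1e-9)
    )
    mask = dm.neighborhood_mask()
    return dm.resample_trees(table, grid, mask)


@pytest.fixture(scope="session")
def cell_stats(landscape, assignment):
    cfg, table, _ = landscape
    return dm.compute_cell_stats(
        assignment, table, reference=dm.reference_sample(cfg)
    )


@pytest.fixture(scope="session")
def two_pop():
    """Sharp-cline landscape with disjoint ancestral allele sets."""
    cfg = dm.LandscapeConfig(
        seed=3,
        n_trees=600,
        disjoint_ancestral=True,
        cline_width=0.05,
        hotspot_allele_prob=0.0,
        clonal_fraction=0.0,
        gap_loci=0,
        f_region=0.0,
    )
    table, truth = dm.simulate_landscape(cfg)
    return cfg, table, truth
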
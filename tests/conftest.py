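import numpy as np
import pytest

import divcontinuum as dc


@pytest.fixture(scope="session")
def small_pair():
    """A modest null simulation shared by read-only tests (no planted regions)."""
    cfg = dc.SimulationConfig(seed=11, chrom_lengths={"chr1": 2_000_000},
                              background_fst=0.15, accessible_fraction=0.9)
    pop1, pop2, truth = dc.simulate_pair(cfg)
    mask = dc.simulated_mask(cfg)
    return cfg, pop1, pop2, mask, truth


@pytest.fixture(scope="session")
def planted_pair():
    """One strong planted region of each signature on a 2 x 8 Mb genome."""
    regions = [
        dc.PlantedRegion("chr1", 1_000_000, 1_030_000, "sweep_pop1", 6.0),
        dc.PlantedRegion("chr1", 5_000_000, 5_030_000, "sweep_pop2", 6.0),
        dc.PlantedRegion("chr2", 2_000_000, 2_030_000, "background_selection", 6.0),
        dc.PlantedRegion("chr2", 6_000_000, 6_030_000, "reduced_gene_flow", 6.0),
    ]
    cfg = dc.SimulationConfig(
        seed=5, chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
        background_fst=0.15, accessible_fraction=0.8, regions=regions)
    pop1, pop2, truth = dc.simulate_pair(cfg)
    mask = dc.simulated_mask(cfg)
    return cfg, pop1, pop2, mask, truth
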
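import warnings

import pytest

from mutprop.library_design import design_library
from mutprop.ngs_processing import process_counts
from mutprop.synthetic_data import SimulationConfig, simulate_counts, simulate_library


@pytest.fixture(scope="session")
def power_sim():
    """Strong planted asymmetry: 4 variants/class, delta 0.9, 5 replicates."""
    cfg = SimulationConfig(seed=1, n_variants_per_class=4, effect_size=0.9,
                           depth=100_000, n_replicates=5)
    lib = simulate_library(cfg)
    designs = design_library(lib.regions, lib.variants,
                             peptide_len=cfg.peptide_len, step=cfg.step)
    table = simulate_counts(designs, lib.truth, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed = process_counts(table)
    return cfg, lib, designs, processed
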
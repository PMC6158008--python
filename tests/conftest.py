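import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ltrperturb.simulate import (  # noqa: E402
    SimConfig,
    simulate_repeat_genome,
)


def small_config(**overrides) -> SimConfig:
    """A genome small enough for dense-scan oracles (<= 200 kb)."""
    base = dict(
        seed=17,
        family_sizes={"LTR5HS": 8, "LTR5A": 4, "LTR5B": 4},
        chrom_lengths={"chr1": 120_000},
        repeat_segments={"chr1": [(10_000, 110_000)]},
        gene_strata=(),
        bound_fraction={"LTR5HS": 0.85, "LTR5A": 0.5, "LTR5B": 0.5},
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    genome, instances, truth = simulate_repeat_genome(cfg)
    return cfg, genome, instances
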
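import warnings

import pytest

from cnasig import SimConfig, generate_cohort
from cnasig.blocks import aggregate, build_blocks

# lifelines emits small-sample / approximation warnings irrelevant to assertions
warnings.filterwarnings("ignore", module="lifelines")


@pytest.fixture(scope="session")
def ref_cohort():
    """Reference simulated cohort (default parameter point, fixed seed)."""
    return generate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def ref_blocks(ref_cohort):
    matrix, probes, clinical, genes, truth = ref_cohort
    blocks = build_blocks(probes, k=10)
    bm = aggregate(matrix, blocks)
    return blocks, bm
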
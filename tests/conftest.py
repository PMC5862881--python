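"""Shared fixtures: a small synthetic cohort and a rearranged-genome
read set, generated once per session."""

from __future__ import annotations

import pytest

from progenomix import breakfast
from progenomix.simulate import (SyntheticCohortConfig, align_and_write_sam,
                                 simulate_expression,
                                 simulate_rearranged_genome, simulate_reads)

# desk-scale cohort: same group design as the full study, fewer genes
SMALL_CONFIG = dict(n_genes=400, n_mirnas=20, targets_per_mirna=3, n_dmrs=15)


@pytest.fixture(scope="session")
def small_config() -> SyntheticCohortConfig:
    return SyntheticCohortConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_expression(small_config, seed=11)


@pytest.fixture(scope="session")
def sv_setup(tmp_path_factory):
    """Error-free reads from a genome with three planted rearrangements,
    aligned back to the reference and written as name-sorted SAM."""
    cfg = SyntheticCohortConfig(base_error_rate=0.0)
    reference, donor, breakends = simulate_rearranged_genome(cfg, seed=3)
    reads = simulate_reads(donor, cfg, seed=103)
    sam = tmp_path_factory.mktemp("sv") / "reads.sam"
    align_and_write_sam(reads, reference, sam)
    return {"config": cfg, "reference": reference, "donor": donor,
            "breakends": breakends, "sam": sam}


# scaled-down discordance span for the 2 x 50 kb test genome
TEST_MAX_SPAN = 5000


@pytest.fixture(scope="session")
def sv_calls(sv_setup):
    return breakfast.call_structural_variants(
        sv_setup["sam"], sv_setup["reference"], max_span=TEST_MAX_SPAN,
        window=1000)
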
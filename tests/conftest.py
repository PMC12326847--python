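"""Shared fixtures: seeded toy genomes and the promoter amplicon scenario."""

import numpy as np
import pytest

from hremeth import (
    AmpliconRef, SyntheticGenome, make_promoter_amplicon, simulate_genome,
)

# TWIST1-style proximal-promoter scenario: twelve CpG sites labelled by their
# position upstream of the TSS, with published per-site percent methylation
# used as planted simulation truth (normoxia / hypoxia).
PROMOTER_SITES = [-242, -231, -218, -214, -210, -200, -177, -162, -144, -123, -101, -81]
PROMOTER_PCT_N = {
    -81: 86, -101: 85, -123: 92, -144: 79, -162: 69, -177: 80,
    -200: 71, -210: 77, -214: 95, -218: 92, -231: 90, -242: 78,
}
PROMOTER_PCT_H = {
    -81: 70, -101: 69, -123: 87, -144: 77, -162: 65, -177: 90,
    -200: 83, -210: 80, -214: 94, -218: 92, -231: 94, -242: 100,
}
PROMOTER_ANCHOR = 1000  # absolute 0-based TSS position in the synthetic contig


def promoter_probs(condition: str) -> np.ndarray:
    """Planted truth in amplicon order (ascending position, -242 first)."""
    table = PROMOTER_PCT_N if condition == "N" else PROMOTER_PCT_H
    return np.array([table[s] for s in PROMOTER_SITES]) / 100.0


@pytest.fixture(scope="session")
def toy_genome() -> SyntheticGenome:
    """5 kb single-contig genome with 5 planted HREs."""
    return simulate_genome(1, 5_000, 0.45, 5, rng_seed=42)


@pytest.fixture(scope="session")
def promoter_genome() -> SyntheticGenome:
    return make_promoter_amplicon(PROMOTER_SITES, anchor_pos=PROMOTER_ANCHOR, rng_seed=5)


@pytest.fixture(scope="session")
def promoter_amplicon(promoter_genome) -> AmpliconRef:
    start, end = PROMOTER_ANCHOR - 242 - 20, PROMOTER_ANCHOR - 81 + 30
    return AmpliconRef.from_genome(
        promoter_genome, "promoter", start, end, tss_anchor=PROMOTER_ANCHOR
    )
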
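"""Shared fixtures: small hand-built datasets, all generated in-memory."""

import numpy as np
import pytest

from phylopop.io_formats import Alignment, GenotypeTable, PopulationMap


@pytest.fixture
def toy_alignment():
    """Two populations of two samples; pop B fixed for a different haplotype."""
    return Alignment(
        ("a1", "a2", "b1", "b2"),
        ("AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAATT", "AAAAAAAATT"),
        "toy",
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap.from_pairs([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")])


@pytest.fixture
def toy_genotypes():
    """Two loci, two populations of 3; pop B fixed for different alleles at L1."""
    calls = np.array(
        [
            # L1,      L2
            [[10, 10], [20, 22]],
            [[10, 10], [20, 20]],
            [[10, 10], [22, 22]],
            [[14, 14], [20, 22]],
            [[14, 14], [22, 22]],
            [[14, 14], [20, 20]],
        ]
    )
    gt = GenotypeTable(
        ("a1", "a2", "a3", "b1", "b2", "b3"), ("L1", "L2"), calls
    )
    popmap = PopulationMap.from_pairs(
        [("a1", "A"), ("a2", "A"), ("a3", "A"), ("b1", "B"), ("b2", "B"), ("b3", "B")]
    )
    return gt, popmap
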
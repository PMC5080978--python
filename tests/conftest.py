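"""Shared builders for simulator-backed tests."""

from __future__ import annotations

import numpy as np
import pytest

from tetramap.simcross import Chromosome, MeiosisConfig, ParentalHaplotypes


def two_locus_parent(
    d1: int, d2: int, overlap: int, dist_cm: float = 10.0, parent_id: str = "P"
) -> ParentalHaplotypes:
    """Parent with two loci whose allele copies overlap on ``overlap``
    homologs (the two-point phase parameterisation)."""
    alleles = np.zeros((4, 2), dtype=np.int8)
    alleles[:d1, 0] = 1
    second = list(range(overlap)) + list(range(d1, d1 + d2 - overlap))
    alleles[second, 1] = 1
    return ParentalHaplotypes(
        parent_id,
        [Chromosome("c1", np.array([0.0, dist_cm]), alleles, ["mA", "mB"])],
    )


def single_locus_parent(d: int, pos_cm: float = 0.0, parent_id: str = "P") -> ParentalHaplotypes:
    alleles = np.zeros((4, 1), dtype=np.int8)
    alleles[:d, 0] = 1
    return ParentalHaplotypes(
        parent_id, [Chromosome("c1", np.array([pos_cm]), alleles, ["m1"])]
    )


def gamete_joint_freq(parent, n: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo 3×3 joint gamete dosage frequencies for a 2-locus parent."""
    from tetramap.simcross import simulate_gametes

    g = simulate_gametes(parent, MeiosisConfig(), n, rng=np.random.default_rng(seed))[0]
    dos = g.sum(axis=1)
    freq = np.zeros((3, 3))
    np.add.at(freq, (dos[:, 0], dos[:, 1]), 1.0)
    return freq / n


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160152)
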
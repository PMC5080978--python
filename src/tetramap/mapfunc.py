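"""Kosambi mapping function and its inverse.

The Kosambi function converts a recombination fraction r into an additive
map distance d = 25·ln((1+2r)/(1−2r)) cM, with implicit crossover
interference.  Its inverse is r = tanh(d/50)/2.  Both accept scalars or
numpy arrays; the forward direction is defined on [0, 0.5) only.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kosambi", "inverse_kosambi"]


def kosambi(r):
    """Map distance in cM for recombination fraction ``r`` in [0, 0.5).

    Raises ``ValueError`` outside the domain (r = 0.5 corresponds to
    unlinked loci and an infinite map distance).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def inverse_kosambi(d):
    """Recombination fraction for a map distance ``d`` ≥ 0 in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r
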
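"""Shared fixtures and hand-rolled oracles used across the suite."""

import numpy as np
import pytest

from delimkit.fixtures import load_case_study
from delimkit.seqdist import DistanceMatrix
from delimkit.synthdata import SimConfig, make_dataset


@pytest.fixture(scope="session")
def case_study():
    return load_case_study()


@pytest.fixture(scope="session")
def default_dataset():
    """One deep-divergence synthetic dataset reused by several tests."""
    return make_dataset(SimConfig(seed=7))


def dm_from_dict(ids, dist, saturated=()):
    """Build a DistanceMatrix from {(a, b): d} for hand-crafted scenarios."""
    ids = tuple(ids)
    n = len(ids)
    idx = {s: i for i, s in enumerate(ids)}
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    sites = np.full((n, n), 100, dtype=int)
    for (a, b), v in dist.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
    for a, b in saturated:
        sat[idx[a], idx[b]] = sat[idx[b], idx[a]] = True
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = np.nan
    return DistanceMatrix(ids=ids, d=d, saturated=sat, sites_used=sites)


# ---------------------------------------------------------------------------
# independent K2P oracle: explicit site-pattern classification table

_PATTERN = {}
for _x in "ACGT":
    for _y in "ACGT":
        if _x == _y:
            _PATTERN[(_x, _y)] = "same"
_PATTERN.update(
    {
        ("A", "G"): "ts", ("G", "A"): "ts",
        ("C", "T"): "ts", ("T", "C"): "ts",
        ("A", "C"): "tv", ("C", "A"): "tv",
        ("A", "T"): "tv", ("T", "A"): "tv",
        ("G", "C"): "tv", ("C", "G"): "tv",
        ("G", "T"): "tv", ("T", "G"): "tv",
    }
)


def oracle_k2p(a, b):
    """Site-pattern-counting K2P oracle; returns (P, Q, d_or_None)."""
    import math
    from collections import Counter

    counts = Counter(
        _PATTERN[(x, y)]
        for x, y in zip(a, b)
        if (x, y) in _PATTERN
    )
    n = counts["same"] + counts["ts"] + counts["tv"]
    if n == 0:
        return None
    p, q = counts["ts"] / n, counts["tv"] / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return p, q, None
    return p, q, -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def random_seq(rng, length=100, alphabet="ACGT-N", gap_frac=0.1):
    chars = list("ACGT")
    seq = rng.choice(chars, size=length)
    mask = rng.random(length) < gap_frac
    extras = rng.choice(["-", "N"], size=length)
    seq = np.where(mask, extras, seq)
    return "".join(seq)
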
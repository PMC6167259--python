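"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings

from mendelburden import Pedigree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# -- independent oracles -------------------------------------------------------

def fraser_fraction_by_enumeration(s: int) -> Fraction:
    """Exact family-limitation averted fraction by exhaustive enumeration.

    Enumerates all 2^s affected/unaffected birth sequences, weighting each
    by its probability under a per-birth recurrence risk of 1/4.  Births
    after the first affected birth are averted; the result is expected
    averted affected births over expected total affected births.  Exact
    rational arithmetic — independent of the closed form it checks.
    """
    p = Fraction(1, 4)
    expected_averted = Fraction(0)
    for pattern in itertools.product((0, 1), repeat=s):
        k = sum(pattern)
        prob = p**k * (1 - p) ** (s - k)
        if 1 in pattern:
            first = pattern.index(1)
            expected_averted += prob * sum(pattern[first + 1:])
    return expected_averted / (Fraction(s) * p)


def fraser_fraction_by_simulation(
    s: int, n_sibships: int, seed: int
) -> tuple[float, float]:
    """Monte Carlo averted fraction and its standard error (delta method).

    Simulates ``n_sibships`` sibships of size ``s`` with per-birth affected
    probability 1/4; averted affected births are those following an earlier
    affected birth in the same sibship.
    """
    rng = np.random.default_rng(seed)
    affected = rng.random((n_sibships, s)) < 0.25
    any_prior = np.cumsum(affected, axis=1) - affected > 0
    averted = (affected & any_prior).sum(axis=1).astype(float)
    total = affected.sum(axis=1).astype(float)
    r = averted.sum() / total.sum()
    # delta-method SE of a ratio of means
    resid = averted - r * total
    se = float(
        np.sqrt(np.var(resid, ddof=1) / n_sibships) / total.mean()
    )
    return float(r), se


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """A random acyclic pedigree with ``n`` members.

    Built sequentially: each new individual is a founder with probability
    0.4 (always, while fewer than two individuals exist) or the child of
    two distinct earlier individuals, so parents always precede children.
    """
    parent_map: dict[str, tuple[str | None, str | None]] = {}
    names = [f"i{k}" for k in range(n)]
    for k, name in enumerate(names):
        if k < 2 or rng.random() < 0.4:
            parent_map[name] = (None, None)
        else:
            f, m = rng.choice(k, size=2, replace=False)
            parent_map[name] = (names[f], names[m])
    return Pedigree(parent_map)


# -- shared pedigree fixtures --------------------------------------------------

@pytest.fixture
def full_sib_pedigree() -> Pedigree:
    """Two founders with two children (full siblings)."""
    return Pedigree(
        {
            "f": (None, None),
            "m": (None, None),
            "s1": ("f", "m"),
            "s2": ("f", "m"),
        }
    )
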
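"""Shared fixtures and independent test oracles."""

import itertools
import math

import pytest

from flavohunt.biotransform_db import (
    builtin_modifier_table,
    builtin_parents,
    enumerate_candidates,
    group_by_formula,
)
from flavohunt.formula_engine import ISOTOPES


@pytest.fixture(scope="session")
def modifiers():
    return builtin_modifier_table()


@pytest.fixture(scope="session")
def naringenin():
    return builtin_parents()[0]


@pytest.fixture(scope="session")
def catechin():
    return builtin_parents()[1]


@pytest.fixture(scope="session")
def flavanonol_groups(naringenin, modifiers):
    """Full default flavanonol candidate database grouped by formula."""
    return group_by_formula(enumerate_candidates(naringenin, modifiers))


@pytest.fixture(scope="session")
def small_groups(naringenin, modifiers):
    """Reduced database (max 3 modifiers) for fast matcher tests."""
    return group_by_formula(
        enumerate_candidates(naringenin, modifiers, max_total=3)
    )


# ---------------------------------------------------------------------------
# independent isotopologue oracle: exhaustive enumeration by polynomial
# expansion (per-element multinomial terms, cartesian product over elements),
# structurally unrelated to the package's sequential convolution
# ---------------------------------------------------------------------------

def _partitions(n, k):
    """All ways to split n identical atoms over k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _partitions(n - first, k - 1):
            yield (first,) + rest


def brute_force_isotope_clusters(counts, n_peaks):
    """Exhaustive isotopologue enumeration aggregated by extra-neutron count.

    Returns a list of (centroid mass, probability) for the first ``n_peaks``
    clusters of the *neutral* molecule, probabilities unnormalised.
    """
    per_element = []
    for el, n in counts.items():
        iso = ISOTOPES[el]
        base = iso[0][0]
        terms = []
        for ks in _partitions(n, len(iso)):
            coeff = math.factorial(n)
            prob = 1.0
            mass = 0.0
            shift = 0
            for k, (m, a) in zip(ks, iso):
                coeff //= math.factorial(k)
                prob *= a ** k
                mass += k * m
                shift += k * round(m - base)
            terms.append((shift, coeff * prob, mass))
        per_element.append(terms)

    clusters = {}
    for combo in itertools.product(*per_element):
        shift = sum(s for s, _, _ in combo)
        prob = 1.0
        for _, p, _ in combo:
            prob *= p
        mass = sum(m for _, _, m in combo)
        acc = clusters.setdefault(shift, [0.0, 0.0])
        acc[0] += prob
        acc[1] += prob * mass
    out = []
    for shift in sorted(clusters)[:n_peaks]:
        p, msum = clusters[shift]
        out.append((msum / p, p))
    return out
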
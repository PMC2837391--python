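"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
Fisher oracle enumerates 2x2 tables with exact integer arithmetic, the BH
oracle is the textbook step-up loop, and the mapping oracle slides a
signature over every offset of every sequence.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import mpsspipe as mp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles

def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by exhaustive
    enumeration of all tables with the observed margins, in exact rational
    arithmetic (sum of point probabilities <= the observed one)."""
    r1, r2 = a + b, c + d
    k1 = a + c
    lo, hi = max(0, k1 - r2), min(k1, r1)
    weight_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, k1 - x)
        if w <= weight_obs:
            total += w
    return Fraction(total, comb(r1 + r2, k1))


def bh_oracle(pvals):
    """Textbook step-up BH: q_(k) = min_{j >= k} p_(j) * m / j, capped at 1."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def mapping_oracle(signature, unigenes, max_mismatches=3, anchor="GATC"):
    """All-offsets scan: a hit is any window (either strand) whose first
    four bases equal the anchor exactly and whose remainder has at most
    ``max_mismatches`` substitutions against the signature."""
    L = len(signature)
    hits = set()
    for uid, seq in unigenes.items():
        for strand in ("+", "-"):
            s = seq if strand == "+" else mp.reverse_complement(seq)
            for off in range(len(s) - L + 1):
                window = s[off:off + L]
                if window[:len(anchor)] != anchor:
                    continue
                if signature[:len(anchor)] != anchor:
                    continue
                mm = sum(1 for x, y in zip(signature[len(anchor):],
                                           window[len(anchor):]) if x != y)
                if mm <= max_mismatches:
                    hits.add((uid, strand, off, mm))
    return hits


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: a few hundred genes, family structure,
    no condition-exclusive genes (those are exercised separately)."""
    return mp.SimulationConfig(seed=7, n_genes=300, n_families=60,
                               family_size_law=("geometric", 3.0),
                               library_depth=200_000, exclusive_counts={})


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mp.generate_dataset(small_config)


@pytest.fixture()
def toy_matrix():
    """Tiny hand-written expression matrix over two libraries."""
    tpm = pd.DataFrame({"L1": [12.0, 5.0, 1500.0], "L2": [0.0, 5.0, 8.0]},
                       index=pd.Index(["s1", "s2", "s3"], name="signature"))
    return mp.ExpressionMatrix(tpm=tpm,
                               totals=pd.Series({"L1": 1000, "L2": 1000}))


def random_counts(rng, n=50, libs=("F", "N", "P", "X"), lam=40):
    tags = []
    while len(tags) < n:
        t = "GATC" + "".join(rng.choice(list("ACGT"), size=17))
        if t not in tags:
            tags.append(t)
    data = rng.poisson(lam, size=(n, len(libs)))
    return pd.DataFrame(data, index=pd.Index(tags, name="signature"),
                        columns=list(libs))
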
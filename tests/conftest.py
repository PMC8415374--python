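"""Shared fixtures: motif sets and trained classifiers reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enhevo.gkm import GappedKmerClassifier
from enhevo.synthetic import make_enhancer, make_motifs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def planted_and_background(motifs, n_each: int, length: int, seed: int):
    """Planted-motif positives and motif-free background sequences."""
    positives = [
        make_enhancer(motifs, length, 0.4, 3, seed=seed * 100_000 + i)[0]
        for i in range(n_each)
    ]
    negatives = [
        make_enhancer(motifs, length, 0.4, 0, seed=seed * 100_000 + 50_000 + i)[0]
        for i in range(n_each)
    ]
    return positives, negatives


def genome_with_planted_enhancers(motifs, n, seed, length=300, spacer=700):
    """A background genome with ``n`` planted enhancers at known intervals."""
    from enhevo.intervals import GenomicInterval

    rng = np.random.default_rng(seed)
    parts, intervals = [], []
    pos = 0
    for i in range(n):
        parts.append(random_sequence(rng, spacer))
        enh = make_enhancer(motifs, length, 0.4, 4, seed=seed * 1000 + i)[0]
        pos += spacer
        intervals.append(GenomicInterval("chrA", pos, pos + length, id=f"p{i}"))
        parts.append(enh)
        pos += length
    parts.append(random_sequence(rng, 5000))
    return {"chrA": "".join(parts)}, intervals


@pytest.fixture(scope="session")
def motifs():
    return make_motifs(3, 8, 1.2, seed=7)


@pytest.fixture(scope="session")
def trained_model(motifs):
    """Default-geometry (l=10, k=6) classifier on planted vs background."""
    pos, neg = planted_and_background(motifs, 60, 300, seed=11)
    model = GappedKmerClassifier(l=10, k=6, random_state=0)
    model.fit(pos + neg, [1] * len(pos) + [0] * len(neg))
    return model


@pytest.fixture(scope="session")
def small_model(motifs):
    """Small-geometry (l=6, k=4) classifier for brute-force comparisons."""
    pos, neg = planted_and_background(motifs, 30, 120, seed=13)
    model = GappedKmerClassifier(l=6, k=4, random_state=0)
    model.fit(pos + neg, [1] * len(pos) + [0] * len(neg))
    return model
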
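"""Shared fixtures: synthetic genomes, a tiered clade, scripted similarities."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from anicode import (AniConfig, CladeSpec, HgtEvent, PairwiseSimilarity,
                     SimilarityCache, balanced_clade_newick,
                     genome_from_contigs, simulate_clade)

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")

_ALPH = np.array(list("ACGT"))


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_ALPH[rng.integers(0, 4, size=length)])


def toy_genome(genome_id: str, length: int = 50, seed: int | None = None):
    """Small random genome; seed defaults to a hash of the id."""
    if seed is None:
        seed = abs(hash(genome_id)) % (2 ** 31)
    return genome_from_contigs(genome_id,
                               [(genome_id, random_sequence(length, seed))])


def make_sim(query_id: str, subject_id: str, ani: float | None,
             pct_aligned: float, n_fragments: int = 100) -> PairwiseSimilarity:
    """Hand-crafted similarity result for assignment-rule tests."""
    n_passed = round(pct_aligned / 100 * n_fragments)
    return PairwiseSimilarity(
        query_id=query_id, subject_id=subject_id, ani_pct=ani,
        pct_aligned_fragments=pct_aligned, n_fragments=n_fragments,
        n_passed=n_passed,
        passed_identities=(ani,) if ani is not None else ())


class ScriptedCache(SimilarityCache):
    """SimilarityCache that serves pre-scripted results by genome_id pair,
    so assignment logic can be tested with exactly controlled ANI values."""

    def __init__(self, sims):
        super().__init__()
        self._sims = {(s.query_id, s.subject_id): s for s in sims}

    def similarity(self, query, subject, config):
        return self._sims[(query.genome_id, subject.genome_id)]


# ---------------------------------------------------------------------------
# simulated clades shared across test modules (session scope: alignment of
# 100 kb genomes is the dominant cost, and permutation studies reuse the
# similarity cache)

#: three families x two genera x two strains; expected identities
#: ~88.1% between families, ~98.5% between genera, ~99.95% between strains,
#: straddling the 95 / 99.5 / 99.9 thresholds with wide margins.
TIERS = [(3, 0.055), (2, 0.00729), (2, 0.00025)]
CLADE_SEED = 73
CLADE_ROOT_LENGTH = 100_000


@pytest.fixture(scope="session")
def tiered_clade():
    spec = CladeSpec(root_length=CLADE_ROOT_LENGTH,
                     newick=balanced_clade_newick(TIERS),
                     seed=CLADE_SEED)
    genomes, ledger = simulate_clade(spec)
    return spec, genomes, ledger


@pytest.fixture(scope="session")
def clade_cache():
    """One similarity cache for every test touching the tiered clade."""
    return SimilarityCache()


@pytest.fixture(scope="session")
def small_clade():
    """4 leaves, 20 kb: two clearly separated pairs for fast unit tests."""
    spec = CladeSpec(root_length=20_000,
                     newick=balanced_clade_newick([(2, 0.04), (2, 0.002)]),
                     seed=11)
    genomes, ledger = simulate_clade(spec)
    return spec, genomes, ledger


@pytest.fixture(scope="session")
def hgt_pair():
    """Two 99.9%-identical 61.2 kb genomes; a 10.2 kb segment of the second
    is replaced by a 30%-diverged donor (10 of its 60 fragments)."""
    spec = CladeSpec(
        root_length=61_200,
        newick="(va:0.0005,vb:0.0005);",
        hgt_events=(HgtEvent(recipient="vb", segment_length=10_200,
                             donor_rate=0.30, start=20_400),),
        seed=19)
    genomes, ledger = simulate_clade(spec)
    return spec, genomes, ledger
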
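import numpy as np
import pytest

from plumprint.model import GenotypeProfile


def make_profile(acc, group, calls):
    return GenotypeProfile(acc, group, {l: frozenset(s) for l, s in calls.items()})


@pytest.fixture
def toy_profiles():
    """Six hand-built hexaploid accessions over three loci, two groups."""
    return [
        make_profile("A1", "G1", {"L1": {100, 104}, "L2": {200}, "L3": {150, 152, 154}}),
        make_profile("A2", "G1", {"L1": {100}, "L2": {200, 202}, "L3": {150}}),
        make_profile("A3", "G1", {"L1": {104}, "L2": {202}, "L3": {150, 152}}),
        make_profile("B1", "G2", {"L1": {108}, "L2": {200}, "L3": {156, 158}}),
        make_profile("B2", "G2", {"L1": {108, 110}, "L2": {204}, "L3": {156}}),
        make_profile("B3", "G2", {"L1": {110}, "L2": {200, 204}, "L3": {158}}),
    ]


def random_profiles(rng, n_acc=10, n_loci=5, n_alleles=4, missing_rate=0.0):
    """Random dominant-scored profiles for property tests."""
    loci = [f"L{i + 1}" for i in range(n_loci)]
    profiles = []
    for a in range(n_acc):
        calls = {}
        for locus in loci:
            if missing_rate and rng.random() < missing_rate:
                continue
            k = int(rng.integers(1, min(n_alleles, 6) + 1))
            sizes = rng.choice(n_alleles, size=k, replace=False)
            calls[locus] = frozenset(100 + 2 * int(s) for s in sizes)
        if not calls:
            calls[loci[0]] = frozenset({100})
        profiles.append(GenotypeProfile(f"A{a:02d}", "G1", calls))
    return profiles
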
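"""Minimal discriminating marker-set selection for cultivar fingerprinting.

Two accessions are *resolved* by a locus subset when their allele sets
differ at some locus of the subset where both were scored; a missing call
acts as a wildcard (a locus neither or only one accession carries cannot
prove them distinct).  The greedy procedure ranks loci by informativeness
(PIC) and adds them until every accession pair is resolved — the field's
usual way of finding a minimal fingerprinting panel.  An exhaustive
subset-enumeration oracle is provided for small panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .model import GenotypeProfile

__all__ = [
    "MarkerSetResult",
    "profiles_distinct",
    "greedy_minimal_set",
    "exhaustive_minimal_set",
]

_MAX_EXHAUSTIVE_LOCI = 15


@dataclass
class MarkerSetResult:
    selected: tuple[str, ...]
    unresolved_per_step: tuple[int, ...]
    resolved: bool
    method: str = "greedy"

    def __post_init__(self) -> None:
        steps = self.unresolved_per_step
        if any(b > a for a, b in zip(steps, steps[1:])):
            raise ValueError("unresolved pair count must be non-increasing")
        if self.resolved != (steps[-1] == 0 if steps else True):
            raise ValueError("resolved flag inconsistent with final pair count")


def profiles_distinct(
    profiles: Sequence[GenotypeProfile], loci: Sequence[str]
) -> set[frozenset[str]]:
    """Accession pairs NOT resolved by the given locus subset.

    A pair is unresolved iff, at every locus of the subset where both
    accessions were scored, their allele sets are identical.
    """
    if not loci:
        raise ValueError("locus subset must be nonempty")
    unresolved: set[frozenset[str]] = set()
    for a, b in combinations(profiles, 2):
        for locus in loci:
            ca, cb = a.calls.get(locus), b.calls.get(locus)
            if ca is not None and cb is not None and ca != cb:
                break
        else:
            unresolved.add(frozenset({a.accession_id, b.accession_id}))
    return unresolved


def greedy_minimal_set(
    profiles: Sequence[GenotypeProfile],
    pic_per_locus: Mapping[str, float],
) -> MarkerSetResult:
    """Add loci in decreasing PIC order until all accessions are resolved.

    Ties in PIC are broken alphabetically by locus name for determinism.
    If the full panel never resolves every pair (duplicate multilocus
    profiles), all loci are returned with ``resolved=False``.
    """
    if len(profiles) < 2:
        return MarkerSetResult(selected=(), unresolved_per_step=(), resolved=True)
    order = sorted(pic_per_locus, key=lambda l: (-pic_per_locus[l], l))
    selected: list[str] = []
    counts: list[int] = []
    for locus in order:
        selected.append(locus)
        n_unresolved = len(profiles_distinct(profiles, selected))
        counts.append(n_unresolved)
        if n_unresolved == 0:
            return MarkerSetResult(tuple(selected), tuple(counts), True)
    return MarkerSetResult(tuple(selected), tuple(counts), False)


def exhaustive_minimal_set(
    profiles: Sequence[GenotypeProfile],
    loci: Sequence[str] | None = None,
) -> MarkerSetResult:
    """Smallest discriminating locus subset by exhaustive enumeration.

    Subsets are tried in order of increasing size, then lexicographically,
    so the result is deterministic.  Refuses panels above 15 loci (2^L
    blow-up); use the greedy procedure there.
    """
    if loci is None:
        loci = sorted({l for p in profiles for l in p.calls})
    loci = sorted(loci)
    if len(loci) > _MAX_EXHAUSTIVE_LOCI:
        raise ValueError(
            f"{len(loci)} loci exceeds the exhaustive-search limit "
            f"({_MAX_EXHAUSTIVE_LOCI}); use greedy_minimal_set"
        )
    if len(profiles) < 2:
        return MarkerSetResult(
            selected=(), unresolved_per_step=(), resolved=True, method="exhaustive"
        )
    for size in range(1, len(loci) + 1):
        for subset in combinations(loci, size):
            unresolved = profiles_distinct(profiles, subset)
            if not unresolved:
                return MarkerSetResult(
                    selected=subset,
                    unresolved_per_step=(0,),
                    resolved=True,
                    method="exhaustive",
                )
    return MarkerSetResult(
        selected=tuple(loci),
        unresolved_per_step=(len(profiles_distinct(profiles, loci)),),
        resolved=False,
        method="exhaustive",
    )
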
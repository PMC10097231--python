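"""Core data model for dominant-scored polyploid SSR genotypes.

European plum (*Prunus domestica*) is hexaploid (2n = 6x = 48), so a single
accession can show up to six distinct fragment lengths at one microsatellite
locus.  Capillary electropherograms cannot resolve allele dosage in a
hexaploid, so genotypes are scored dominantly: per locus, the *set* of
distinct allele sizes (in bp) that the accession carries.  Everything
downstream — frequencies, heterozygosity, PIC, distances, admixture — is
built on these allele-presence sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "LocusDef",
    "MarkerPanel",
    "GenotypeProfile",
    "AlleleMatrix",
    "FrequencyTable",
    "LocusSummary",
    "AlleleClassification",
    "PLOIDY",
]

#: Hexaploid ceiling on distinct alleles per locus per accession.
PLOIDY = 6

_VALID_DYES = {"6-FAM", "HEX", "ATTO550"}


@dataclass(frozen=True)
class LocusDef:
    """One SSR locus: primer pair, fluorescent dye and annealing temperature."""

    name: str
    forward_primer: str
    reverse_primer: str
    dye: str
    annealing_temp_c: int
    reference: str = ""

    def __post_init__(self) -> None:
        for primer in (self.forward_primer, self.reverse_primer):
            if not primer or set(primer) - set("ACGT"):
                raise ValueError(
                    f"locus {self.name!r}: primer must be nonempty ACGT, got {primer!r}"
                )
        if self.dye not in _VALID_DYES:
            raise ValueError(f"locus {self.name!r}: unknown dye {self.dye!r}")
        if not 40 <= self.annealing_temp_c <= 72:
            raise ValueError(
                f"locus {self.name!r}: annealing temperature "
                f"{self.annealing_temp_c} outside [40, 72] degrees C"
            )


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered set of SSR loci used to fingerprint a germplasm collection."""

    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        names = [locus.name for locus in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("panel locus names must be unique")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(locus.name for locus in self.loci)

    def __contains__(self, name: str) -> bool:
        return name in self.locus_names

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class GenotypeProfile:
    """One accession's dominant-scored SSR calls.

    ``calls`` maps locus name to the set of distinct allele sizes (bp)
    observed; a locus absent from the map is a missing call.  Sets hold
    1..6 positive integers (< 1000 bp).
    """

    accession_id: str
    group: str
    calls: dict[str, frozenset[int]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[int]] = {}
        for locus, sizes in self.calls.items():
            sizes = frozenset(int(s) for s in sizes)
            if not 1 <= len(sizes) <= PLOIDY:
                raise ValueError(
                    f"accession {self.accession_id!r}, locus {locus!r}: "
                    f"{len(sizes)} distinct alleles (must be 1..{PLOIDY})"
                )
            if any(s <= 0 or s >= 1000 for s in sizes):
                raise ValueError(
                    f"accession {self.accession_id!r}, locus {locus!r}: "
                    f"allele sizes must be positive integers < 1000"
                )
            clean[locus] = sizes
        self.calls = clean

    def loci(self) -> frozenset[str]:
        return frozenset(self.calls)


@dataclass
class AlleleMatrix:
    """Binary allele-presence matrix (accessions x (locus, size) bands).

    ``values`` holds 1 (band present), 0 (absent) or -1 (locus missing for
    that accession; excluded from frequency denominators and from pairwise
    distances).  ``monomorphic`` flags columns present in every scoreable
    accession.
    """

    accession_ids: tuple[str, ...]
    columns: tuple[tuple[str, int], ...]  # (locus, allele size)
    values: "np.ndarray"  # int8, shape (n_accessions, n_columns)
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.accession_ids), len(self.columns)):
            raise ValueError("matrix shape does not match ids/columns")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("matrix values must be -1 (missing), 0 or 1")

    @property
    def monomorphic(self) -> tuple[bool, ...]:
        flags = []
        for j in range(self.values.shape[1]):
            col = self.values[:, j]
            scored = col[col >= 0]
            flags.append(bool(len(scored)) and bool((scored == 1).all()))
        return tuple(flags)


@dataclass
class FrequencyTable:
    """Carrier frequencies p_i (percent of accessions carrying an allele).

    ``entries`` maps (group, locus, allele size) -> percentage in (0, 100];
    an allele is listed under a group iff at least one accession of that
    group carries it.  ``group_sizes`` records the number of accessions per
    group (the denominators' upper bound; per-locus denominators may be
    smaller when calls are missing).
    """

    entries: dict[tuple[str, str, int], float]
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for key, p in self.entries.items():
            if not 0 < p <= 100:
                raise ValueError(f"frequency out of (0, 100] at {key}: {p}")

    def group_slice(self, group: str) -> dict[tuple[str, int], float]:
        """All (locus, size) -> p_i entries for one group."""
        return {
            (locus, size): p
            for (g, locus, size), p in self.entries.items()
            if g == group
        }

    def groups(self) -> frozenset[str]:
        return frozenset(g for g, _, _ in self.entries)


@dataclass
class LocusSummary:
    """Per-locus, per-group diversity summary row.

    Mirrors the usual germplasm-characterization table: allele count, size
    range, observed heterozygosity Ho (fraction of accessions with >= 2
    distinct alleles), dominant-marker PIC, and the maximum number of
    distinct alleles seen in any single genotype.
    """

    locus: str
    group: str
    allele_number: int
    size_range: tuple[int, int]
    ho: float | None
    pic: float | None
    max_alleles_in_genotype: int | None = None

    def __post_init__(self) -> None:
        if self.allele_number < 1:
            raise ValueError("allele_number must be >= 1")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range min > max")
        if self.ho is not None and not 0 <= self.ho <= 1:
            raise ValueError(f"Ho out of [0,1]: {self.ho}")
        if self.pic is not None and not 0 <= self.pic <= 0.5 + 1e-12:
            raise ValueError(f"PIC out of [0,0.5]: {self.pic}")
        if self.max_alleles_in_genotype is not None and not (
            1 <= self.max_alleles_in_genotype <= PLOIDY
        ):
            raise ValueError("max_alleles_in_genotype out of 1..6")


@dataclass
class AlleleClassification:
    """Partition of polymorphic alleles into common / group-unique, with rarity.

    ``records`` is a list of dicts with keys: locus, size, category (one of
    'common', 'unique_a', 'unique_b'), rare (bool; every nonzero group
    frequency <= the rare threshold), freq_a, freq_b (percent, 0 if absent).
    Category counts and their percentages of the pooled total are exposed by
    :meth:`counts` / :meth:`percentages`.
    """

    records: list[dict]
    rare_threshold: float = 10.0
    group_a: str = "A"
    group_b: str = "B"

    CATEGORIES = ("common", "unique_a", "unique_b")

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.CATEGORIES}
        for rec in self.records:
            out[rec["category"]] += 1
        out["total"] = len(self.records)
        return out

    def rare_counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.CATEGORIES}
        for rec in self.records:
            if rec["rare"]:
                out[rec["category"]] += 1
        out["total"] = sum(out[c] for c in self.CATEGORIES)
        return out

    def percentages(self) -> dict[str, float]:
        """Category shares of the pooled total, percent at 1 decimal."""
        n = len(self.records)
        counts = self.counts()
        if n == 0:
            return {c: 0.0 for c in self.CATEGORIES}
        return {c: round(100.0 * counts[c] / n, 1) for c in self.CATEGORIES}


def distinct_allele_count(profiles: Iterable[GenotypeProfile]) -> int:
    """Number of distinct (locus, size) pairs observed across profiles."""
    seen: set[tuple[str, int]] = set()
    for prof in profiles:
        for locus, sizes in prof.calls.items():
            seen.update((locus, s) for s in sizes)
    return len(seen)
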
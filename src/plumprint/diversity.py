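"""Per-locus diversity statistics for dominant-scored polyploid SSR data.

Because allele dosage is unobservable in a hexaploid electropherogram, all
statistics here are carrier-based:

* allele frequency ``p_i`` — percentage of a group's accessions carrying
  the allele (among those with a non-missing call at the locus);
* observed heterozygosity ``Ho`` — fraction of accessions displaying two
  or more distinct alleles at the locus;
* ``PIC`` — the dominant-marker (band-wise) form ``2 f (1 - f)`` averaged
  over a locus's alleles, with maximum 0.5 at f = 0.5.

Alleles are classified between two accession groups as *common* (carried in
both), *unique* (carried in exactly one — a marker of a population's genetic
individuality) and *rare* (every nonzero group frequency at or below a
threshold, 10% by default).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .model import (
    AlleleClassification,
    FrequencyTable,
    GenotypeProfile,
    LocusSummary,
)

__all__ = [
    "allele_frequencies",
    "frequency_table",
    "observed_heterozygosity",
    "pic_dominant",
    "locus_summary_table",
    "summary_means",
    "classify_alleles",
    "homozygosity_report",
]

POOLED_GROUP = "pooled"


def _group_profiles(
    profiles: Sequence[GenotypeProfile], group: str
) -> list[GenotypeProfile]:
    if group == POOLED_GROUP:
        return list(profiles)
    subset = [p for p in profiles if p.group == group]
    if not subset:
        raise ValueError(f"no accessions in group {group!r}")
    return subset


def allele_frequencies(
    profiles: Sequence[GenotypeProfile], group: str
) -> dict[tuple[str, int], float]:
    """Carrier frequencies p_i (percent) for one group.

    p_i = 100 x (group accessions carrying the allele) / (group accessions
    with a non-missing call at the locus).  The reserved group name
    ``"pooled"`` pools every profile regardless of label.
    """
    subset = _group_profiles(profiles, group)
    carriers: dict[tuple[str, int], int] = {}
    denominators: dict[str, int] = {}
    for prof in subset:
        for locus, sizes in prof.calls.items():
            denominators[locus] = denominators.get(locus, 0) + 1
            for size in sizes:
                carriers[(locus, size)] = carriers.get((locus, size), 0) + 1
    return {
        (locus, size): 100.0 * count / denominators[locus]
        for (locus, size), count in carriers.items()
    }


def frequency_table(
    profiles: Sequence[GenotypeProfile], groups: Sequence[str]
) -> FrequencyTable:
    """Carrier-frequency table over several groups (see allele_frequencies)."""
    entries: dict[tuple[str, str, int], float] = {}
    sizes: dict[str, int] = {}
    for group in groups:
        subset = _group_profiles(profiles, group)
        sizes[group] = len(subset)
        for (locus, size), p in allele_frequencies(profiles, group).items():
            entries[(group, locus, size)] = p
    return FrequencyTable(entries=entries, group_sizes=sizes)


def observed_heterozygosity(
    profiles: Sequence[GenotypeProfile], group: str, locus: str
) -> float | None:
    """Fraction of the group's accessions with >= 2 distinct alleles at locus.

    Returns None when every call at the locus is missing.
    """
    subset = _group_profiles(profiles, group)
    calls = [p.calls[locus] for p in subset if locus in p.calls]
    if not calls:
        return None
    return sum(1 for c in calls if len(c) >= 2) / len(calls)


def pic_dominant(frequencies: Sequence[float]) -> float:
    """Dominant-marker PIC: mean over a locus's alleles of 2 f (1 - f).

    ``frequencies`` are carrier frequencies as fractions in (0, 1].
    """
    freqs = list(frequencies)
    if not freqs:
        raise ValueError("pic_dominant needs at least one allele frequency")
    if any(not 0 < f <= 1 for f in freqs):
        raise ValueError("frequencies must be fractions in (0, 1]")
    return sum(2.0 * f * (1.0 - f) for f in freqs) / len(freqs)


def locus_summary_table(
    profiles: Sequence[GenotypeProfile], groups: Sequence[str]
) -> list[LocusSummary]:
    """Per-locus x per-group summary rows (allele number, size range, Ho, PIC).

    Loci appear in sorted-name order within each group; a locus with no
    non-missing call in a group is skipped.
    """
    rows: list[LocusSummary] = []
    for group in groups:
        subset = _group_profiles(profiles, group)
        freqs = allele_frequencies(profiles, group)
        loci = sorted({l for p in subset for l in p.calls})
        for locus in loci:
            locus_freqs = [p for (l, _), p in freqs.items() if l == locus]
            sizes = sorted(s for (l, s) in freqs if l == locus)
            max_alleles = max(
                len(p.calls[locus]) for p in subset if locus in p.calls
            )
            rows.append(
                LocusSummary(
                    locus=locus,
                    group=group,
                    allele_number=len(sizes),
                    size_range=(min(sizes), max(sizes)),
                    ho=observed_heterozygosity(profiles, group, locus),
                    pic=round(pic_dominant([f / 100.0 for f in locus_freqs]), 3),
                    max_alleles_in_genotype=max_alleles,
                )
            )
    return rows


def summary_means(rows: Sequence[LocusSummary]) -> dict[str, dict[str, float]]:
    """Per-group column means over summary rows.

    Mirrors the "Average" row of a printed characterization table: mean
    allele number, Ho and max-alleles-per-genotype at 2 decimals, PIC at
    3 (its printed precision).  Rounding is half-up to match printed
    tables.
    """
    import math
    from collections import defaultdict

    def round2(x: float) -> float:
        return math.floor(x * 100 + 0.5) / 100

    def round3(x: float) -> float:
        return math.floor(x * 1000 + 0.5) / 1000

    grouped: dict[str, list[LocusSummary]] = defaultdict(list)
    for row in rows:
        grouped[row.group].append(row)
    out: dict[str, dict[str, float]] = {}
    for group, members in grouped.items():
        n = len(members)
        means = {
            "allele_number": round2(sum(m.allele_number for m in members) / n),
            "ho": round2(sum(m.ho for m in members if m.ho is not None) / n),
            "pic": round3(sum(m.pic for m in members if m.pic is not None) / n),
        }
        if all(m.max_alleles_in_genotype is not None for m in members):
            means["max_alleles_in_genotype"] = round2(
                sum(m.max_alleles_in_genotype for m in members) / n
            )
        out[group] = means
    return out


def classify_alleles(
    freq_a: Mapping[tuple[str, int], float],
    freq_b: Mapping[tuple[str, int], float],
    rare_threshold: float = 10.0,
    group_a: str = "A",
    group_b: str = "B",
) -> AlleleClassification:
    """Partition alleles into common / unique-to-A / unique-to-B, with rarity.

    ``freq_a`` / ``freq_b`` map (locus, size) to carrier percentage for the
    two groups (alleles absent from a group simply do not appear in its
    map).  An allele is *common* iff present in both maps, *unique*
    otherwise; *rare* iff every group frequency carrying it is at or below
    ``rare_threshold`` percent.
    """
    records = []
    for key in sorted(set(freq_a) | set(freq_b)):
        pa, pb = freq_a.get(key, 0.0), freq_b.get(key, 0.0)
        if pa > 0 and pb > 0:
            category = "common"
        elif pa > 0:
            category = "unique_a"
        else:
            category = "unique_b"
        carried = [p for p in (pa, pb) if p > 0]
        records.append(
            {
                "locus": key[0],
                "size": key[1],
                "category": category,
                "rare": max(carried) <= rare_threshold,
                "freq_a": pa,
                "freq_b": pb,
            }
        )
    return AlleleClassification(
        records=records,
        rare_threshold=rare_threshold,
        group_a=group_a,
        group_b=group_b,
    )


def homozygosity_report(
    profiles: Sequence[GenotypeProfile], group: str
) -> dict[str, list[str]]:
    """Per accession, the loci showing exactly one distinct allele.

    Accessions are returned ranked by descending single-allele locus count
    (dict order); an accession showing two or more alleles at every scored
    locus maps to an empty list.
    """
    subset = _group_profiles(profiles, group)
    report = {
        prof.accession_id: sorted(
            locus for locus, sizes in prof.calls.items() if len(sizes) == 1
        )
        for prof in subset
    }
    return dict(sorted(report.items(), key=lambda kv: (-len(kv[1]), kv[0])))
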
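"""Reading, writing and binning of dominant-scored SSR genotype data.

The on-disk genotype table is a TSV/CSV with header
``accession<TAB>group<TAB><locus1><TAB>...``; each per-locus cell is a
``/``-separated list of allele sizes in bp (``124/128/134``) and an empty
cell marks a missing call.  The module also bundles fixtures transcribing
the printed summary tables of the Lithuanian plum germplasm study this
package reanalyses: per-locus characteristics of the Lithuanian-origin and
reference cultivar groups (``table1``), the allele catalogue with common /
unique columns and rare-allele bolding (``table2``), the hybrids-vs-parents
comparison (``table3``) and the nine-locus ECPGR marker panel (``table4``).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .model import (
    PLOIDY,
    AlleleClassification,
    AlleleMatrix,
    FrequencyTable,
    GenotypeProfile,
    LocusDef,
    LocusSummary,
    MarkerPanel,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "bin_fragment_sizes",
    "to_binary_matrix",
    "write_structure_format",
    "load_fixture",
    "Table2Fixture",
]

_SIZE_SEP = "/"


def read_genotype_table(
    path: str | Path,
    panel: MarkerPanel | None = None,
    known_groups: Sequence[str] | None = None,
) -> list[GenotypeProfile]:
    """Read a genotype table (TSV or CSV by extension) into profiles.

    Loci not present in ``panel`` (when given) are rejected with an error;
    duplicate sizes within a cell are deduplicated; more than six distinct
    sizes at one locus is a hard error naming the accession and locus.
    """
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if not header or len(header) < 3:
            raise ValueError(f"{path}: expected header 'accession, group, <loci...>'")
        loci = [h.strip() for h in header[2:]]
        if panel is not None:
            bad = [l for l in loci if l not in panel]
            if bad:
                raise ValueError(f"{path}: loci not in panel: {', '.join(bad)}")
        profiles: list[GenotypeProfile] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            accession, group = row[0].strip(), row[1].strip()
            if known_groups is not None and group not in known_groups:
                warnings.warn(
                    f"{path}:{lineno}: unknown group label {group!r} "
                    f"for accession {accession!r}; kept verbatim"
                )
            calls: dict[str, frozenset[int]] = {}
            for locus, cell in zip(loci, row[2:]):
                cell = cell.strip()
                if not cell:
                    continue
                sizes = set()
                for token in cell.split(_SIZE_SEP):
                    token = token.strip()
                    try:
                        sizes.add(int(token))
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric allele size {token!r} "
                            f"at locus {locus!r}"
                        ) from None
                if len(sizes) > PLOIDY:
                    raise ValueError(
                        f"{path}:{lineno}: accession {accession!r} has "
                        f"{len(sizes)} distinct alleles at locus {locus!r} "
                        f"(hexaploid ceiling is {PLOIDY})"
                    )
                calls[locus] = frozenset(sizes)
            profiles.append(GenotypeProfile(accession, group, calls))
    return profiles


def write_genotype_table(
    profiles: Sequence[GenotypeProfile],
    path: str | Path,
    panel: MarkerPanel | None = None,
) -> None:
    """Write profiles as a TSV/CSV genotype table (inverse of the reader)."""
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    loci = list(panel.locus_names) if panel is not None else sorted(
        {l for p in profiles for l in p.calls}
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["accession", "group", *loci])
        for prof in profiles:
            row = [prof.accession_id, prof.group]
            for locus in loci:
                sizes = prof.calls.get(locus)
                row.append(
                    _SIZE_SEP.join(str(s) for s in sorted(sizes)) if sizes else ""
                )
            writer.writerow(row)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def bin_fragment_sizes(
    raw_sizes: Iterable[float], min_step: int = 2
) -> dict[float, int]:
    """Cluster fractional fragment sizes into integer allele bins.

    Capillary sizing drifts by a few bp between runs and instruments, so raw
    sizes are clustered by single linkage: sorted sizes closer than
    ``min_step`` to their neighbour join one bin, labelled by the rounded
    median of the bin's members.  The mapping is monotone (a larger raw size
    never maps to a smaller bin).  A bin spanning three or more steps
    triggers an over-merge warning.
    """
    if min_step < 1:
        raise ValueError("min_step must be >= 1")
    raws = sorted(set(float(s) for s in raw_sizes))
    if any(s <= 0 for s in raws):
        raise ValueError("raw sizes must be positive")
    if not raws:
        return {}
    clusters: list[list[float]] = [[raws[0]]]
    for size in raws[1:]:
        if size - clusters[-1][-1] < min_step:
            clusters[-1].append(size)
        else:
            clusters.append([size])
    mapping: dict[float, int] = {}
    for cluster in clusters:
        if cluster[-1] - cluster[0] >= min_step * 3:
            warnings.warn(
                f"fragment-size bin spanning {cluster[0]}-{cluster[-1]} bp "
                f"exceeds {min_step * 3} bp; alleles may be over-merged"
            )
        label = _round_half_up(median(cluster))
        for raw in cluster:
            mapping[raw] = label
    return mapping


def to_binary_matrix(
    profiles: Sequence[GenotypeProfile],
    panel: MarkerPanel | None = None,
) -> AlleleMatrix:
    """Recode allele-set profiles as a dominant 0/1 band matrix.

    Columns are (locus, allele size) pairs ordered by panel locus order
    (alphabetical when no panel is given) then ascending size.  A missing
    locus call yields -1 in all that locus's columns, excluding the
    accession from frequency denominators and pairwise comparisons.
    Monomorphic columns are flagged on the result, not dropped.
    """
    if not profiles:
        raise ValueError("no profiles given")
    observed: dict[str, set[int]] = {}
    for prof in profiles:
        for locus, sizes in prof.calls.items():
            observed.setdefault(locus, set()).update(sizes)
    if panel is not None:
        locus_order = [l for l in panel.locus_names if l in observed]
    else:
        locus_order = sorted(observed)
    columns = tuple(
        (locus, size) for locus in locus_order for size in sorted(observed[locus])
    )
    values = np.zeros((len(profiles), len(columns)), dtype=np.int8)
    for i, prof in enumerate(profiles):
        for j, (locus, size) in enumerate(columns):
            call = prof.calls.get(locus)
            if call is None:
                values[i, j] = -1
            elif size in call:
                values[i, j] = 1
    return AlleleMatrix(
        accession_ids=tuple(p.accession_id for p in profiles),
        columns=columns,
        values=values,
        groups=tuple(p.group for p in profiles),
    )


def write_structure_format(
    profiles: Sequence[GenotypeProfile],
    path: str | Path,
    panel: MarkerPanel | None = None,
) -> None:
    """Write profiles in the admixture-sampler raw text layout.

    Each accession occupies six rows (one per homologous chromosome copy in
    a hexaploid).  Per locus, the observed distinct allele sizes fill the
    first slots once each in ascending order; remaining slots — dosage being
    unobservable — are coded -9 (missing), as is every slot of an entirely
    missing locus.
    """
    loci = list(panel.locus_names) if panel is not None else sorted(
        {l for p in profiles for l in p.calls}
    )
    with open(path, "w") as fh:
        fh.write("\t".join(["accession", *loci]) + "\n")
        for prof in profiles:
            slots: dict[str, list[int]] = {}
            for locus in loci:
                sizes = sorted(prof.calls.get(locus, ()))
                slots[locus] = sizes + [-9] * (PLOIDY - len(sizes))
            for k in range(PLOIDY):
                row = [prof.accession_id] + [str(slots[locus][k]) for locus in loci]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Bundled fixtures


@dataclass
class Table2Fixture:
    """Verbatim transcription of the printed allele catalogue.

    Each record is one printed table entry: locus, allele size, the column
    it appeared in (``common``, ``unique_lt``, ``unique_ref``), its printed
    carrier frequency in percent, and whether the entry was printed in bold
    (the table's rare-allele flag).  The transcription preserves the printed
    table's quirks — one allele listed in two columns and one bold flag
    inconsistent with the stated frequency rule — so analyses against the
    printed values and against the rule can be compared.
    """

    records: list[dict]
    group_a: str = "LT-origin"
    group_b: str = "R-Plum"

    _CAT_MAP = {"common": "common", "unique_lt": "unique_a", "unique_ref": "unique_b"}

    def counts(self) -> dict[str, int]:
        out = {"common": 0, "unique_lt": 0, "unique_ref": 0}
        for rec in self.records:
            out[rec["category"]] += 1
        out["total"] = len(self.records)
        return out

    def group_allele_counts(self) -> dict[str, int]:
        """Alleles per group: common entries plus the group's unique entries."""
        c = self.counts()
        return {
            self.group_a: c["common"] + c["unique_lt"],
            self.group_b: c["common"] + c["unique_ref"],
        }

    def max_frequency(self) -> float:
        return max(rec["freq_pct"] for rec in self.records)

    def to_classification(self, rare_threshold: float = 10.0) -> AlleleClassification:
        """Classify the printed entries, deriving rarity from the frequency rule.

        Categories come from the printed column membership; the rare flag is
        recomputed as ``freq <= rare_threshold`` (the printed bold flags are
        carried separately on each record as ``printed_rare``).
        """
        out = []
        for rec in self.records:
            category = self._CAT_MAP[rec["category"]]
            freq = rec["freq_pct"]
            out.append(
                {
                    "locus": rec["locus"],
                    "size": rec["allele_size"],
                    "category": category,
                    "rare": freq <= rare_threshold,
                    "printed_rare": rec["printed_rare"],
                    "freq_a": freq if category in ("common", "unique_a") else 0.0,
                    "freq_b": freq if category in ("common", "unique_b") else 0.0,
                }
            )
        return AlleleClassification(
            records=out,
            rare_threshold=rare_threshold,
            group_a=self.group_a,
            group_b=self.group_b,
        )

    def to_frequency_table(self, n_lt: int = 14, n_ref: int = 6) -> FrequencyTable:
        """Expand to per-group frequency entries.

        Common alleles carry the printed (pooled) percentage under both
        groups; unique alleles only under their own group.  The duplicate
        printed entry collapses here, so the general set-membership
        classifier sees 156 distinct (group, locus, size) alleles where the
        printed table lists 157 entries.
        """
        entries: dict[tuple[str, str, int], float] = {}
        for rec in self.records:
            key_a = (self.group_a, rec["locus"], rec["allele_size"])
            key_b = (self.group_b, rec["locus"], rec["allele_size"])
            if rec["category"] in ("common", "unique_lt"):
                entries[key_a] = rec["freq_pct"]
            if rec["category"] in ("common", "unique_ref"):
                entries[key_b] = rec["freq_pct"]
        return FrequencyTable(entries=entries, group_sizes={self.group_a: n_lt, self.group_b: n_ref})


def _fixture_path(name: str):
    return resources.files("plumprint.fixtures").joinpath(f"{name}.csv")


def _load_summary_fixture(name: str, with_max: bool) -> list[LocusSummary]:
    rows = []
    with _fixture_path(name).open(newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                LocusSummary(
                    locus=rec["locus"],
                    group=rec["group"],
                    allele_number=int(rec["allele_number"]),
                    size_range=(int(rec["size_min"]), int(rec["size_max"])),
                    ho=float(rec["ho"]),
                    pic=float(rec["pic"]),
                    max_alleles_in_genotype=(
                        int(rec["max_alleles"]) if with_max else None
                    ),
                )
            )
    return rows


def load_fixture(name: str):
    """Load a bundled printed-table fixture.

    ``table1`` / ``table3`` return lists of :class:`LocusSummary` (cultivar
    groups / hybrids-vs-parents), ``table2`` a :class:`Table2Fixture`, and
    ``table4`` the nine-locus :class:`MarkerPanel`.
    """
    if name == "table1":
        return _load_summary_fixture("table1", with_max=True)
    if name == "table3":
        return _load_summary_fixture("table3", with_max=False)
    if name == "table2":
        records = []
        with _fixture_path("table2").open(newline="") as fh:
            for rec in csv.DictReader(fh):
                records.append(
                    {
                        "locus": rec["locus"],
                        "allele_size": int(rec["allele_size"]),
                        "category": rec["category"],
                        "freq_pct": float(rec["freq_pct"]),
                        "printed_rare": rec["printed_rare"] == "1",
                    }
                )
        return Table2Fixture(records=records)
    if name == "table4":
        loci = []
        with _fixture_path("table4").open(newline="") as fh:
            for rec in csv.DictReader(fh):
                loci.append(
                    LocusDef(
                        name=rec["locus"],
                        forward_primer=rec["forward_primer"],
                        reverse_primer=rec["reverse_primer"],
                        dye=rec["dye"],
                        annealing_temp_c=int(rec["annealing_temp_c"]),
                        reference=rec["reference"],
                    )
                )
        return MarkerPanel(loci=tuple(loci))
    raise ValueError(f"unknown fixture {name!r}; expected table1..table4")
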
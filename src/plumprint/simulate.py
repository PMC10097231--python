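"""Synthetic hexaploid SSR genotype generator.

Emulates the statistical structure of a dominant-scored plum germplasm
panel: several accession groups with group-differentiated allele
frequencies, hexaploid genotypes recorded as distinct-allele sets (dosage
discarded), pedigree crosses whose offspring inherit three allele copies
from each parent, and Gaussian fragment-sizing jitter.  Defaults mirror the
scale of a two-group cultivar study: nine SSR loci with 8–21 alleles each
on a dinucleotide (2 bp) size grid, 14 + 6 accessions.

Under the six-copy sampling model, an allele at frequency f is *carried*
(appears in the distinct set) with probability 1 - (1 - f)^6 — the
transform frequency-level tests must apply when comparing empirical carrier
frequencies with simulated copy frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import bin_fragment_sizes
from .model import PLOIDY, GenotypeProfile, LocusDef, MarkerPanel

__all__ = [
    "SimConfig",
    "SimulatedPanel",
    "simulate_panel",
    "simulate_groups",
    "simulate_cross",
    "add_size_noise",
    "binned_recovery_rate",
    "carrier_probability",
]

_PLACEHOLDER_FWD = "ACGTACGTACGTACGTACGT"
_PLACEHOLDER_REV = "TGCATGCATGCATGCATGCA"
_DYES = ("6-FAM", "HEX", "ATTO550")


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    ``concentration`` is the symmetric Dirichlet parameter for per-group
    allele frequencies: small values (<1) give skewed, group-differentiated
    frequencies; large values push all groups toward the same near-uniform
    spectrum.  ``disjoint_pools`` instead partitions each locus's allele
    pool between groups (maximal differentiation, zero common alleles).
    """

    n_loci: int = 9
    alleles_per_locus: tuple[int, int] = (8, 21)
    size_grid_start: int = 96
    size_grid_step: int = 2
    group_sizes: tuple[int, ...] = (14, 6)
    concentration: float = 0.5
    disjoint_pools: bool = False
    crosses: tuple[tuple[str, str, int], ...] = ()
    size_jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or any(n < 1 for n in self.group_sizes):
            raise ValueError("counts must be positive")
        if self.size_grid_step < 2:
            raise ValueError("size grid step must be >= 2")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        lo, hi = self.alleles_per_locus
        if not 1 <= lo <= hi:
            raise ValueError("invalid alleles_per_locus range")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(len(self.group_sizes)))


@dataclass
class SimulatedPanel:
    panel: MarkerPanel
    pools: dict[str, tuple[int, ...]]  # locus -> allele sizes on the grid


def simulate_panel(cfg: SimConfig) -> SimulatedPanel:
    """Draw a marker panel and per-locus allele pools on the size grid.

    Loci are named SIM001, SIM002, ...; each locus gets a pool of
    consecutive grid sizes starting at a random offset, so all alleles of a
    locus share parity when the step is 2.  Primers are placeholders.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = []
    pools: dict[str, tuple[int, ...]] = {}
    lo, hi = cfg.alleles_per_locus
    for i in range(cfg.n_loci):
        name = f"SIM{i + 1:03d}"
        n_alleles = int(rng.integers(lo, hi + 1))
        start = cfg.size_grid_start + int(rng.integers(0, 40)) * cfg.size_grid_step
        pools[name] = tuple(
            start + k * cfg.size_grid_step for k in range(n_alleles)
        )
        loci.append(
            LocusDef(
                name=name,
                forward_primer=_PLACEHOLDER_FWD,
                reverse_primer=_PLACEHOLDER_REV,
                dye=_DYES[i % len(_DYES)],
                annealing_temp_c=58,
                reference="simulated",
            )
        )
    return SimulatedPanel(panel=MarkerPanel(loci=tuple(loci)), pools=pools)


def simulate_groups(cfg: SimConfig, sim_panel: SimulatedPanel) -> list[GenotypeProfile]:
    """Draw group-structured hexaploid profiles.

    Per group x locus, allele copy frequencies ~ symmetric
    Dirichlet(concentration); per accession, six allele copies are drawn
    i.i.d. from the group's frequencies and collapsed to the distinct set.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    profiles: list[GenotypeProfile] = []
    loci = sim_panel.panel.locus_names
    freqs: dict[tuple[str, str], tuple[np.ndarray, tuple[int, ...]]] = {}
    for g, group in enumerate(cfg.group_names):
        for locus in loci:
            pool = sim_panel.pools[locus]
            if cfg.disjoint_pools:
                share = [
                    size for k, size in enumerate(pool)
                    if k % len(cfg.group_sizes) == g
                ]
                pool = tuple(share) if share else pool[:1]
            f = rng.dirichlet(np.full(len(pool), cfg.concentration))
            freqs[(group, locus)] = (f, pool)
    counter = 0
    for group, n_acc in zip(cfg.group_names, cfg.group_sizes):
        for _ in range(n_acc):
            counter += 1
            calls = {}
            for locus in loci:
                f, pool = freqs[(group, locus)]
                copies = rng.choice(len(pool), size=PLOIDY, replace=True, p=f)
                calls[locus] = frozenset(pool[c] for c in copies)
            profiles.append(GenotypeProfile(f"ACC{counter:03d}", group, calls))
    return profiles


def _six_copy_expansion(sizes: frozenset[int]) -> list[int]:
    ordered = sorted(sizes)
    return [ordered[i % len(ordered)] for i in range(PLOIDY)]


def simulate_cross(
    parent_a: GenotypeProfile,
    parent_b: GenotypeProfile,
    n_offspring: int,
    seed: int = 0,
) -> list[GenotypeProfile]:
    """Balanced hexaploid cross: each offspring gets 3 + 3 parental copies.

    Per locus, each parent's distinct-allele set is cycled into a six-copy
    expansion; three copies are sampled without replacement from each
    parent's expansion and the union's distinct set is the offspring call.
    Offspring allele sets are therefore always subsets of the parental
    union.  A locus missing in either parent is missing in the offspring.
    """
    rng = np.random.default_rng(seed)
    offspring = []
    shared = sorted(set(parent_a.calls) & set(parent_b.calls))
    for i in range(n_offspring):
        calls = {}
        for locus in shared:
            copies: list[int] = []
            for parent in (parent_a, parent_b):
                expansion = _six_copy_expansion(parent.calls[locus])
                picked = rng.choice(PLOIDY, size=PLOIDY // 2, replace=False)
                copies.extend(expansion[k] for k in picked)
            calls[locus] = frozenset(copies)
        offspring.append(
            GenotypeProfile(
                accession_id=f"{parent_a.accession_id}x{parent_b.accession_id}-{i + 1}",
                group="hybrid",
                calls=calls,
                metadata={
                    "pedigree": f"{parent_a.accession_id} x {parent_b.accession_id}"
                },
            )
        )
    return offspring


def add_size_noise(
    profiles: Sequence[GenotypeProfile], jitter_sd: float, seed: int = 0
) -> dict[tuple[str, str], dict[int, float]]:
    """Gaussian sizing jitter: per call, map true size -> raw fractional bp.

    Returns {(accession_id, locus): {true size: raw size}}.  Feeding the
    pooled raw sizes through fragment binning recovers the true integers
    when the jitter is small relative to the inter-allele spacing.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    raw: dict[tuple[str, str], dict[int, float]] = {}
    for prof in profiles:
        for locus, sizes in sorted(prof.calls.items()):
            raw[(prof.accession_id, locus)] = {
                size: size + float(rng.normal(0.0, jitter_sd))
                for size in sorted(sizes)
            }
    return raw


def binned_recovery_rate(
    profiles: Sequence[GenotypeProfile],
    raw_calls: dict[tuple[str, str], dict[int, float]],
    min_step: int = 2,
) -> float:
    """Fraction of calls whose binned raw sizes equal the true allele set.

    Raw sizes are pooled per locus across accessions (the usual panel-wide
    binning practice), clustered with :func:`bin_fragment_sizes`, and each
    call's raw sizes are mapped back through the pooled bins.
    """
    per_locus: dict[str, list[float]] = {}
    for (_, locus), call in raw_calls.items():
        per_locus.setdefault(locus, []).extend(call.values())
    bins = {
        locus: bin_fragment_sizes(raws, min_step=min_step)
        for locus, raws in per_locus.items()
    }
    total = hits = 0
    for prof in profiles:
        for locus, sizes in prof.calls.items():
            call = raw_calls[(prof.accession_id, locus)]
            recovered = frozenset(bins[locus][raw] for raw in call.values())
            total += 1
            hits += recovered == sizes
    return hits / total if total else 1.0


def carrier_probability(f: float, ploidy: int = PLOIDY) -> float:
    """P(allele appears in the distinct set) given its copy frequency f."""
    return 1.0 - (1.0 - f) ** ploidy
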
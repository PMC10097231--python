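"""Bayesian admixture clustering for dosage-unknown hexaploid SSR data.

The model is the standard admixture mixture: each accession n has a
proportion vector Q_n over K ancestral clusters, each cluster k carries
per-locus allele frequencies P_k, and every observed allele copy is an
independent draw — its cluster origin Z from Q_n, its allele from P_k at
the locus.  Genotypes enter in the six-slot layout used for polyploid
dominant data: per locus the distinct observed alleles fill the first
slots once each and the remaining slots are coded -9 (missing, skipped in
all likelihood terms), exactly how a dosage-blind polyploid dataset is fed
to admixture software.

Inference is by Gibbs sampling with conjugate updates: Z | (Q, P)
slot-wise categorical; P | Z Dirichlet(lambda + counts) with lambda = 1;
Q | Z Dirichlet(alpha + counts) with fixed symmetric alpha = 1 (no alpha
updating — a deliberate simplification adequate for model-choice via
Evanno's Delta-K).  The reported lnP(X|K) is the posterior mean of the
data log-likelihood over post-burn-in sweeps, a simpler estimator than the
harmonic-mean correction used by the original software; it is consistent
across K within this package, which is all Delta-K comparisons need.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import PLOIDY, GenotypeProfile

__all__ = [
    "StructureData",
    "StructureRun",
    "EvannoResult",
    "read_structure_file",
    "gibbs_fit",
    "run_grid",
    "evanno_delta_k",
    "align_q",
    "q_bar_plot",
]

MISSING = -9


@dataclass
class StructureData:
    """Six-slot integer-coded genotypes plus per-locus allele code books."""

    accessions: tuple[str, ...]
    loci: tuple[str, ...]
    slots: np.ndarray  # (n, n_loci, 6) allele indices, MISSING where absent
    allele_codes: tuple[tuple[int, ...], ...]  # per locus, index -> allele size

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=np.int64)
        if self.slots.shape != (len(self.accessions), len(self.loci), PLOIDY):
            raise ValueError("slots array shape mismatch")

    @property
    def n_alleles(self) -> tuple[int, ...]:
        return tuple(len(codes) for codes in self.allele_codes)

    @classmethod
    def from_profiles(cls, profiles: Sequence[GenotypeProfile],
                      loci: Sequence[str] | None = None) -> "StructureData":
        if loci is None:
            loci = sorted({l for p in profiles for l in p.calls})
        loci = tuple(loci)
        pools: dict[str, set[int]] = {l: set() for l in loci}
        for prof in profiles:
            for locus in loci:
                pools[locus].update(prof.calls.get(locus, ()))
        keep = [l for l in loci if pools[l]]
        dropped = [l for l in loci if not pools[l]]
        if dropped:
            warnings.warn(f"dropping all-missing loci: {', '.join(dropped)}")
        codes = tuple(tuple(sorted(pools[l])) for l in keep)
        index = [{size: i for i, size in enumerate(c)} for c in codes]
        slots = np.full((len(profiles), len(keep), PLOIDY), MISSING, dtype=np.int64)
        for i, prof in enumerate(profiles):
            for j, locus in enumerate(keep):
                sizes = sorted(prof.calls.get(locus, ()))
                for k, size in enumerate(sizes):
                    slots[i, j, k] = index[j][size]
        return cls(
            accessions=tuple(p.accession_id for p in profiles),
            loci=tuple(keep),
            slots=slots,
            allele_codes=codes,
        )

    def profiles_back(self) -> dict[str, dict[str, frozenset[int]]]:
        """Distinct-allele sets per accession (inverse of the writer layout)."""
        out: dict[str, dict[str, frozenset[int]]] = {}
        for i, acc in enumerate(self.accessions):
            calls = {}
            for j, locus in enumerate(self.loci):
                observed = self.slots[i, j][self.slots[i, j] != MISSING]
                if len(observed):
                    calls[locus] = frozenset(
                        self.allele_codes[j][a] for a in observed
                    )
            out[acc] = calls
        return out


def read_structure_file(path: str | Path) -> StructureData:
    """Read the six-row-per-accession raw text layout written by genotype_io."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "accession":
            raise ValueError(f"{path}: expected header starting with 'accession'")
        loci = tuple(header[1:])
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) % PLOIDY:
        raise ValueError(f"{path}: row count not a multiple of {PLOIDY}")
    accessions: list[str] = []
    raw: list[np.ndarray] = []
    for start in range(0, len(rows), PLOIDY):
        block = rows[start : start + PLOIDY]
        labels = {r[0] for r in block}
        if len(labels) != 1:
            raise ValueError(f"{path}: inconsistent accession labels {labels}")
        accessions.append(block[0][0])
        raw.append(np.array([[int(x) for x in r[1:]] for r in block]).T)
    sizes = np.stack(raw)  # (n, n_loci, 6) of allele sizes or -9
    pools = [
        tuple(sorted(set(sizes[:, j].ravel()) - {MISSING}))
        for j in range(len(loci))
    ]
    slots = np.full_like(sizes, MISSING)
    for j, pool in enumerate(pools):
        index = {size: i for i, size in enumerate(pool)}
        for size, code in index.items():
            slots[:, j][sizes[:, j] == size] = code
    return StructureData(
        accessions=tuple(accessions),
        loci=loci,
        slots=slots,
        allele_codes=tuple(pools),
    )


@dataclass
class StructureRun:
    """One Gibbs run: its settings, lnP(X|K) and posterior-mean Q and P."""

    K: int
    seed: int
    burn_in: int
    iterations: int
    lnP: float
    Q: np.ndarray  # (n, K) posterior mean admixture proportions
    P: np.ndarray  # (K, n_loci, max_alleles) posterior mean frequencies
    lnP_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not math.isfinite(self.lnP):
            raise ValueError("lnP must be finite")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")


def gibbs_fit(
    data: StructureData,
    K: int,
    burn_in: int = 2000,
    iterations: int = 5000,
    seed: int = 0,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> StructureRun:
    """Fit the admixture model at a fixed K by Gibbs sampling.

    ``iterations`` post-burn-in sweeps are averaged for lnP, Q and P.
    A fixed seed gives bit-identical output.  K larger than the accession
    count is permitted (with a warning) — clusters can stay empty.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_acc, n_loci = len(data.accessions), len(data.loci)
    if K > n_acc:
        warnings.warn(f"K={K} exceeds accession count {n_acc}")
    rng = np.random.default_rng(seed)

    obs = np.argwhere(data.slots != MISSING)
    acc_idx = obs[:, 0]
    loc_idx = obs[:, 1]
    allele_idx = data.slots[obs[:, 0], obs[:, 1], obs[:, 2]]
    n_obs = len(acc_idx)
    max_alleles = max(data.n_alleles)
    valid = np.zeros((n_loci, max_alleles), dtype=bool)
    for j, count in enumerate(data.n_alleles):
        valid[j, :count] = True

    def dirichlet_rows(shape_param: np.ndarray, mask: np.ndarray) -> np.ndarray:
        gam = rng.gamma(np.where(mask, shape_param, 1.0))
        gam = np.where(mask, gam, 0.0)
        total = gam.sum(axis=-1, keepdims=True)
        return gam / total

    # init: random cluster assignment per observed slot
    z = rng.integers(0, K, size=n_obs)

    q_sum = np.zeros((n_acc, K))
    p_sum = np.zeros((K, n_loci, max_alleles))
    trace = np.empty(iterations)
    flat_loc_allele = loc_idx * max_alleles + allele_idx

    for sweep in range(burn_in + iterations):
        # P | Z: per-cluster Dirichlet(lam + allele counts)
        counts_p = np.zeros((K, n_loci * max_alleles))
        np.add.at(counts_p, (z, flat_loc_allele), 1.0)
        counts_p = counts_p.reshape(K, n_loci, max_alleles)
        P = dirichlet_rows(lam + counts_p, np.broadcast_to(valid, counts_p.shape))

        # Q | Z: per-accession Dirichlet(alpha + origin counts)
        counts_q = np.zeros((n_acc, K))
        np.add.at(counts_q, (acc_idx, z), 1.0)
        Q = dirichlet_rows(alpha + counts_q, np.ones_like(counts_q, dtype=bool))

        # Z | (Q, P): slot-wise categorical
        w = Q[acc_idx] * P[:, loc_idx, allele_idx].T  # (n_obs, K)
        totals = w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        u = rng.random(n_obs)[:, None] * totals
        z = (u >= cum).sum(axis=1)

        if sweep >= burn_in:
            loglik = float(np.log(totals).sum())
            trace[sweep - burn_in] = loglik
            q_sum += Q
            p_sum += P

    Q_mean = q_sum / iterations
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    P_mean = p_sum / iterations
    return StructureRun(
        K=K,
        seed=seed,
        burn_in=burn_in,
        iterations=iterations,
        lnP=float(trace.mean()),
        Q=Q_mean,
        P=P_mean,
        lnP_trace=trace,
    )


def grid_seed(seed_base: int, K: int, run: int) -> int:
    return seed_base * 1000 + K * 100 + run


def run_grid(
    data: StructureData,
    k_range: Sequence[int] = range(1, 21),
    runs_per_k: int = 10,
    burn_in: int = 2000,
    iterations: int = 5000,
    seed_base: int = 0,
    progress: bool = False,
) -> list[StructureRun]:
    """Independent Gibbs runs over a K grid with derived, distinct seeds."""
    runs: list[StructureRun] = []
    for K in k_range:
        for r in range(runs_per_k):
            seed = grid_seed(seed_base, K, r)
            if progress:
                print(f"structure: K={K} run={r} seed={seed}", flush=True)
            runs.append(
                gibbs_fit(data, K, burn_in=burn_in, iterations=iterations, seed=seed)
            )
    return runs


@dataclass
class EvannoResult:
    """Delta-K table: per K the mean/sd of lnP over runs and the derived stats.

    ``table`` maps K -> dict with keys mean, sd, l_prime, l_second_abs,
    delta_k (None where undefined: boundary K, or fewer than 2 runs).
    ``best_k`` is the K maximizing Delta-K; ``ranked`` lists candidate Ks
    by decreasing Delta-K.
    """

    table: dict[int, dict[str, float | None]]
    best_k: int | None
    ranked: tuple[int, ...]


def evanno_delta_k(runs: Sequence[StructureRun]) -> EvannoResult:
    """Second-difference model choice: Delta-K = |L''(K)| / sd(L(K)).

    L(K) is the mean lnP over replicate runs at K; L''(K) the second
    difference over consecutive K.  Needs at least three consecutive K
    values with at least two runs each for any Delta-K to be defined.
    A zero sd yields an infinite Delta-K with a warning.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.lnP)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {
        k: (float(np.std(by_k[k], ddof=1)) if len(by_k[k]) >= 2 else None)
        for k in ks
    }
    table: dict[int, dict[str, float | None]] = {}
    for k in ks:
        l_prime = mean[k] - mean[k - 1] if k - 1 in mean else None
        l_second = (
            abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            if (k - 1 in mean and k + 1 in mean)
            else None
        )
        delta = None
        if l_second is not None and sd[k] is not None:
            if sd[k] == 0:
                warnings.warn(f"zero sd of lnP at K={k}; Delta-K is infinite")
                delta = math.inf
            else:
                delta = l_second / sd[k]
        table[k] = {
            "mean": mean[k],
            "sd": sd[k],
            "l_prime": l_prime,
            "l_second_abs": l_second,
            "delta_k": delta,
        }
    ranked = tuple(
        sorted(
            (k for k in ks if table[k]["delta_k"] is not None),
            key=lambda k: -table[k]["delta_k"],
        )
    )
    return EvannoResult(table=table, best_k=ranked[0] if ranked else None, ranked=ranked)


def align_q(runs: Sequence[StructureRun]) -> np.ndarray:
    """Average Q across runs after greedy cluster-label alignment.

    Cluster labels are arbitrary per run; columns of each run's Q are
    matched to the first run's by greedily pairing the most-correlated
    columns, then the aligned matrices are averaged (rows still sum to 1).
    """
    if not runs:
        raise ValueError("no runs given")
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share K")
    ref = runs[0].Q
    total = ref.copy()
    for run in runs[1:]:
        q = run.Q
        if K == 1:
            total += q
            continue
        corr = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                a, b = ref[:, i], q[:, j]
                sa, sb = a.std(), b.std()
                corr[i, j] = (
                    float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0
                    else -float(np.abs(a - b).sum())
                )
        perm = np.full(K, -1)
        used_i, used_j = set(), set()
        for _ in range(K):
            best, bi, bj = -np.inf, -1, -1
            for i in range(K):
                if i in used_i:
                    continue
                for j in range(K):
                    if j in used_j:
                        continue
                    if corr[i, j] > best:
                        best, bi, bj = corr[i, j], i, j
            perm[bi] = bj
            used_i.add(bi)
            used_j.add(bj)
        total += q[:, perm]
    mean = total / len(runs)
    return mean / mean.sum(axis=1, keepdims=True)


_BLOCKS = "0123456789"


def q_bar_plot(q: np.ndarray, labels: Sequence[str], width: int = 40) -> str:
    """Plain-text bar rendering of a Q matrix (one row per accession).

    Each accession's bar is ``width`` characters; cluster k occupies a
    share of the bar proportional to Q[n, k], drawn with digit k.
    """
    lines = []
    label_w = max(len(l) for l in labels)
    for n, label in enumerate(labels):
        counts = np.floor(q[n] * width).astype(int)
        while counts.sum() < width:
            counts[int(np.argmax(q[n] * width - counts))] += 1
        bar = "".join(_BLOCKS[k % 10] * counts[k] for k in range(q.shape[1]))
        lines.append(f"{label:<{label_w}} |{bar}|")
    return "\n".join(lines)
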
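"""End-to-end orchestration: genotypes in, full report bundle out.

A pipeline run loads (or simulates) dominant-scored SSR profiles, then
chains the analysis stages: per-group diversity summaries, two-group
allele classification, minimal discriminating marker set, bootstrap UPGMA
dendrogram, and the admixture run grid with Evanno Delta-K.  Every stage
logs its parameters; all randomness flows from the config seeds, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import diversity, markers, phylogeny, structure
from .genotype_io import (
    load_fixture,
    read_genotype_table,
    to_binary_matrix,
    write_structure_format,
)
from .simulate import SimConfig, simulate_groups, simulate_panel

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full run (YAML-serializable, versioned schema).

    ``mode`` is one of ``tsv`` (read ``input_path``), ``simulate`` (use the
    ``sim`` block) or ``fixture`` (analyze the bundled printed allele
    catalogue; only the classification stage applies).  Full-scale presets
    (1000 bootstrap replicates; K 1..20, 10 runs, burn-in 200000, 500000
    iterations) match a published-study scale; ``desk=True`` scales them
    down for interactive work and testing.
    """

    schema_version: int = 1
    mode: str = "simulate"
    input_path: str | None = None
    groups: tuple[str, ...] = ()
    rare_threshold: float = 10.0
    metric: str = "dice"
    bootstrap_replicates: int = 1000
    k_min: int = 1
    k_max: int = 20
    runs_per_k: int = 10
    burn_in: int = 200_000
    iterations: int = 500_000
    seed: int = 0
    desk: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "plumprint_out"

    def __post_init__(self) -> None:
        if self.mode not in ("tsv", "simulate", "fixture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.rare_threshold <= 100:
            raise ValueError("rare_threshold must be in (0, 100]")

    def effective(self) -> dict:
        """Stage parameters after applying the desk preset, if any."""
        if not self.desk:
            return {
                "bootstrap": self.bootstrap_replicates,
                "k_min": self.k_min,
                "k_max": self.k_max,
                "runs_per_k": self.runs_per_k,
                "burn_in": self.burn_in,
                "iterations": self.iterations,
            }
        return {
            "bootstrap": min(self.bootstrap_replicates, 200),
            "k_min": self.k_min,
            "k_max": min(self.k_max, 6),
            "runs_per_k": min(self.runs_per_k, 5),
            "burn_in": min(self.burn_in, 500),
            "iterations": min(self.iterations, 1000),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: tuple(v) if k == "groups" else v for k, v in raw.items()})
        if sim_raw:
            for key in ("alleles_per_locus", "group_sizes", "crosses"):
                if key in sim_raw:
                    sim_raw[key] = tuple(
                        tuple(x) if isinstance(x, list) else x for x in sim_raw[key]
                    )
            cfg.sim = SimConfig(**sim_raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_classification(cls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus,size,category,rare,freq_a,freq_b\n")
        for rec in cls.records:
            fh.write(
                f"{rec['locus']},{rec['size']},{rec['category']},"
                f"{int(rec['rare'])},{rec['freq_a']:g},{rec['freq_b']:g}\n"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; return a manifest of outputs and results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eff = config.effective()
    log: list[str] = [f"config hash: {config.config_hash()}"]
    manifest: dict = {"out_dir": str(out), "config_hash": config.config_hash()}

    if config.mode == "fixture":
        fixture = load_fixture("table2")
        cls = fixture.to_classification(rare_threshold=config.rare_threshold)
        _write_classification(cls, out / "classification.csv")
        manifest["classification"] = cls.counts()
        log.append(f"fixture classification: {cls.counts()}")
        (out / "report.txt").write_text("\n".join(log) + "\n")
        return manifest

    if config.mode == "tsv":
        if not config.input_path:
            raise ValueError("tsv mode requires input_path")
        profiles = read_genotype_table(config.input_path)
    else:
        sim_panel = simulate_panel(config.sim)
        profiles = simulate_groups(config.sim, sim_panel)
    if not profiles:
        raise ValueError("no input profiles")
    groups = list(config.groups) or sorted({p.group for p in profiles})
    log.append(f"loaded {len(profiles)} profiles; groups: {', '.join(groups)}")

    # --- diversity summaries ------------------------------------------------
    rows = diversity.locus_summary_table(profiles, groups)
    with open(out / "summary.csv", "w") as fh:
        fh.write("locus,group,allele_number,size_min,size_max,ho,pic,max_alleles\n")
        for r in rows:
            fh.write(
                f"{r.locus},{r.group},{r.allele_number},{r.size_range[0]},"
                f"{r.size_range[1]},{r.ho:.2f},{r.pic:.3f},"
                f"{r.max_alleles_in_genotype}\n"
            )
    manifest["summary_means"] = diversity.summary_means(rows)

    if len(groups) >= 2:
        freq_a = diversity.allele_frequencies(profiles, groups[0])
        freq_b = diversity.allele_frequencies(profiles, groups[1])
        cls = diversity.classify_alleles(
            freq_a, freq_b, config.rare_threshold, groups[0], groups[1]
        )
        _write_classification(cls, out / "classification.csv")
        manifest["classification"] = cls.counts()

    # --- minimal marker set -------------------------------------------------
    pooled = diversity.allele_frequencies(profiles, diversity.POOLED_GROUP)
    loci = sorted({l for p in profiles for l in p.calls})
    pic_map = {
        locus: diversity.pic_dominant(
            [p / 100 for (l, _), p in pooled.items() if l == locus]
        )
        for locus in loci
    }
    minset = markers.greedy_minimal_set(profiles, pic_map)
    (out / "minset.json").write_text(
        json.dumps(
            {
                "selected": list(minset.selected),
                "unresolved_per_step": list(minset.unresolved_per_step),
                "resolved": minset.resolved,
                "pic": {l: round(pic_map[l], 3) for l in minset.selected},
            },
            indent=2,
        )
        + "\n"
    )
    manifest["minset"] = list(minset.selected)
    log.append(f"minimal marker set: {minset.selected} resolved={minset.resolved}")

    # --- dendrogram ---------------------------------------------------------
    matrix = to_binary_matrix(profiles)
    tree = phylogeny.bootstrap_support(
        matrix,
        metric=config.metric,
        replicates=eff["bootstrap"],
        seed=config.seed,
    )
    phylogeny.write_newick(tree, out / "tree.nwk", min_support=30.0)
    with open(out / "cophenetic.csv", "w") as fh:
        fh.write("a,b,distance\n")
        for i, a in enumerate(tree.ids):
            for j in range(i + 1, len(tree.ids)):
                fh.write(f"{a},{tree.ids[j]},{tree.cophenetic[i, j]:.6f}\n")
    manifest["tree"] = str(out / "tree.nwk")
    log.append(
        f"UPGMA tree: {len(tree.ids)} leaves, metric={config.metric}, "
        f"bootstrap={eff['bootstrap']}, seed={config.seed}"
    )

    # --- admixture grid -----------------------------------------------------
    str_path = out / "genotypes.str"
    write_structure_format(profiles, str_path)
    data = structure.read_structure_file(str_path)
    runs = structure.run_grid(
        data,
        k_range=range(eff["k_min"], eff["k_max"] + 1),
        runs_per_k=eff["runs_per_k"],
        burn_in=eff["burn_in"],
        iterations=eff["iterations"],
        seed_base=config.seed,
    )
    with open(out / "structure_runs.csv", "w") as fh:
        fh.write("K,run,seed,lnP\n")
        for idx, run in enumerate(runs):
            fh.write(f"{run.K},{idx % eff['runs_per_k']},{run.seed},{run.lnP:.4f}\n")
    evanno = structure.evanno_delta_k(runs)
    with open(out / "evanno.csv", "w") as fh:
        fh.write("K,mean_lnP,sd_lnP,l_prime,l_second_abs,delta_k\n")
        for k, row in evanno.table.items():
            cells = [
                f"{row[c]:.4f}" if row[c] is not None else ""
                for c in ("mean", "sd", "l_prime", "l_second_abs", "delta_k")
            ]
            fh.write(f"{k}," + ",".join(cells) + "\n")
    best = evanno.best_k
    manifest["best_k"] = best
    if best is not None:
        q_mean = structure.align_q([r for r in runs if r.K == best])
        with open(out / "q_matrix.csv", "w") as fh:
            fh.write("accession," + ",".join(f"Q{k + 1}" for k in range(best)) + "\n")
            for n, acc in enumerate(data.accessions):
                fh.write(acc + "," + ",".join(f"{x:.4f}" for x in q_mean[n]) + "\n")
        (out / "q_barplot.txt").write_text(
            structure.q_bar_plot(q_mean, data.accessions) + "\n"
        )
    log.append(f"admixture grid: {eff}; Delta-K best K = {best}")

    (out / "report.txt").write_text("\n".join(log) + "\n")
    return manifest
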
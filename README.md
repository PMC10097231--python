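# plumprint

SSR fingerprinting and genetic-diversity analysis for **hexaploid plum
germplasm** (*Prunus domestica*), built for curators and breeders who score
microsatellite fragments dominantly because allele dosage cannot be read
from a polyploid electropherogram.

European plum is hexaploid (2n = 6x = 48), so one accession can show up to
six distinct fragment lengths at a locus. `plumprint` treats a genotype as
a per-locus *set* of allele sizes (bp) and provides, on top of that model:

* **Diversity statistics** — carrier allele frequencies
  *p<sub>i</sub>* = % of accessions carrying a band; observed
  heterozygosity *H<sub>o</sub>* = fraction of accessions showing ≥ 2
  distinct alleles at a locus; dominant-marker
  **PIC** = mean over a locus's bands of 2*f*(1 − *f*) (maximum 0.5 at
  *f* = 0.5).
* **Allele classification** — *common* (carried by both accession groups),
  *unique* (one group only; a marker of a population's genetic
  individuality) and *rare* (every carrying group's *p<sub>i</sub>* ≤ 10%).
* **Minimal fingerprinting panels** — loci added greedily in decreasing
  PIC order until every accession pair is distinguished, with an exhaustive
  subset-enumeration oracle for verification.
* **UPGMA dendrograms** — Dice/Jaccard/simple-matching distances on the
  0/1 band matrix, size-weighted average linkage, column-bootstrap clade
  support, Newick output.
* **Bayesian admixture clustering** — a Gibbs sampler for the standard
  admixture model on six-slot, `-9`-padded polyploid genotypes, a run grid
  over K, and **Evanno ΔK** = |L″(K)| / sd(L(K)) model choice.
* **A synthetic hexaploid genotype generator** — group-differentiated
  Dirichlet allele frequencies, balanced 3+3 pedigree crosses, fragment-size
  jitter — so every stage is testable end to end without external data.

The package also bundles machine-readable transcriptions of a published
nine-locus ECPGR plum marker panel and its printed per-locus summary and
allele-catalogue tables, used as exact regression fixtures.

## Worked example

```python
import plumprint as pp

# classify the bundled allele catalogue (two cultivar groups, nine loci)
fixture = pp.load_fixture("table2")
cls = fixture.to_classification(rare_threshold=10)
print(cls.counts())
print(cls.percentages())
```

prints

```
{'common': 79, 'unique_a': 62, 'unique_b': 16, 'total': 157}
{'common': 50.3, 'unique_a': 39.5, 'unique_b': 10.2}
```

i.e. of 157 polymorphic alleles, 79 (50.3%) are carried by both cultivar
groups, 62 (39.5%) only by the Lithuanian-origin group and 16 (10.2%) only
by the reference group.

A full synthetic run, from simulation to dendrogram and ΔK:

```python
from plumprint import SimConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    mode="simulate",
    sim=SimConfig(group_sizes=(15, 15, 15), concentration=0.15, seed=1),
    desk=True, seed=1, out_dir="demo_out",
)
manifest = run_pipeline(cfg)
print(manifest["best_k"])   # -> 3 (the simulated group count)
```

The same stages are exposed on the command line:

```sh
plumprint simulate --out genotypes.tsv --seed 1
plumprint stats   --in genotypes.tsv --groups G1,G2 --out summary.csv
plumprint minset  --in genotypes.tsv --method greedy --out minset.json
plumprint tree    --in genotypes.tsv --metric dice --bootstrap 1000 --seed 42 --out tree.nwk
plumprint convert --in genotypes.tsv --structure genotypes.str
plumprint structure --in genotypes.str --kmin 1 --kmax 6 --runs 5 \
    --burnin 500 --iters 1000 --seed 7 --out runs.csv
```

## Layout

| module | contents |
| --- | --- |
| `plumprint.model` | core types: marker panel, genotype profile, band matrix, frequency table |
| `plumprint.genotype_io` | TSV/CSV readers and writers, fragment-size binning, six-slot admixture format, bundled fixtures |
| `plumprint.diversity` | frequencies, H<sub>o</sub>, PIC, summary tables, allele classification |
| `plumprint.markers` | greedy and exhaustive minimal discriminating marker sets |
| `plumprint.phylogeny` | band distances, UPGMA, bootstrap support, Newick |
| `plumprint.structure` | admixture Gibbs sampler, run grid, Evanno ΔK, Q alignment |
| `plumprint.simulate` | synthetic hexaploid panel/group/cross generator, sizing noise |
| `plumprint.pipeline`, `plumprint.cli` | end-to-end orchestration and the `plumprint` command |

See `docs/methods.md` for the statistical model, defaults and limitations.
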
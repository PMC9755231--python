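# microtpl

Taylor power-law extension (PLE) analysis of host-associated microbiome
OTU tables, built around the question: *how spatially heterogeneous are the
bacterial communities living on a host's skin, and does that heterogeneity
depend on how much skin the host offers?*

It is aimed at microbial ecologists with an OTU (operational taxonomic
unit) count table, per-sample host metadata, and optionally an OTU-to-phylum
taxonomy.

## The model

Taylor's power law relates the variance *V* of abundance to its mean *M*:

    V = a · M^b        ⇔        ln V = ln a + b · ln M

The slope *b* is the heterogeneity scaling parameter: *b* < 1 indicates a
uniform (regular) spatial distribution, *b* = 1 a random one, *b* > 1
aggregation.  Two community-level extensions of the law are fitted:

* **Type-I** — one (M, V) pair per sample: mean and variance across all
  OTUs in that sample.  The slope *b₁* measures community spatial
  heterogeneity.
* **Type-III** — one (M, V) pair per OTU: mean and variance of that OTU
  across samples (the "mixed-species population").  The slope *b₃*
  measures how heterogeneously a given taxon is spread across hosts.

Fits are done overall, per host species, and restricted to the dominant
phyla.  Per-host-species slopes are then regressed on the species' mean
skin area, computed from morphometric traits with an equivalent-geometry
model (head = cone, trunk = cylinder; a 2D silhouette model serves as
cross-validation).  Supporting statistics — Shannon alpha diversity,
Kruskal–Wallis tests across hosts, Bray–Curtis dissimilarity and the ANOSIM
permutation test — are included, as is a synthetic-study generator that
produces OTU tables with a *known* target slope so that every stage of the
pipeline is testable without any sequencing data.

## Worked example

Simulate a four-species study (40 samples, species-specific OTU blocks plus
a shared core, an aggregated Type-III law with target b = 1.8) and run the
whole pipeline:

```sh
cat > demo.cfg <<EOF
n_species=4
total_samples=40
otus_per_species=80
n_shared_otus=40
permutations=999
EOF
microtpl run-all --config demo.cfg --simulate --seed 2026 --out-dir demo
```

The run logs `ANOSIM R=1.000 p=0.001`: host species are perfectly separated
in composition (every between-species Bray–Curtis distance exceeds every
within-species one), and with 999 permutations the p-value is at its floor
of 1/1000.  `demo/ple_fits.tsv` then holds the fitted laws, e.g.

| group_label | level    | n_points | b     | b_ci_low | b_ci_high | r2    | class      |
|-------------|----------|----------|-------|----------|-----------|-------|------------|
| all         | type_I   | 40       | 1.904 | 1.547    | 2.262     | 0.754 | aggregated |
| all         | type_III | 360      | 1.753 | 1.705    | 1.800     | 0.936 | aggregated |
| Species_01  | type_III | 120      | 1.863 | 1.795    | 1.932     | 0.961 | aggregated |

The overall Type-III slope (1.753) recovers the generator's target of 1.8
to within its confidence interval's neighbourhood, every per-species slope
is classified *aggregated* (CI entirely above 1), and the Type-I points are
visibly more scattered (lower r²) than the Type-III points — the pattern
expected when community-level heterogeneity varies more between hosts than
any single taxon does.  `demo/trends.tsv` regresses the per-species slopes
on species mean skin area and finds no significant trend (p ≥ 0.33 for all
four level × area-kind combinations): heterogeneity is scale-invariant in
this simulated study, by construction.

The same subcommands work on real data: `microtpl fit-tple --otu-table
otus.tsv --metadata meta.tsv --group-by species --out fits.tsv`, plus
`area`, `diversity`, `scale-invariance` and `simulate` (see `--help`).

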
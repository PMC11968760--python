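# twobrad

Species-level microbiome profiling from type IIB restriction (2bRAD) tags,
with the comparative statistics used in two-group, low-biomass studies —
built for microbiome researchers who want the whole computation, from
reference genomes to biomarker panels, reproducible from a single seed.

Type IIB enzymes such as BcgI cut on both sides of their recognition site
(`CGA·N6·TGC`) and release uniform 32 bp fragments.  Sequencing only these
fragments samples every genome at an enzyme-defined set of loci, which
makes species identification a matter of exact tag lookup: a **marker** is
a tag that occurs single-copy in a genome of its species and in no other
species.  For a sample, with `S_i` reads assigned to species *i*'s markers,
`t_i` distinct markers observed and `T_i` theoretical markers in the
database, the pipeline reports species passing the false-positive filter

    G_i = sqrt(S_i * t_i) >= 5

with coverage-normalised relative abundances

    a_i = (S_i / T_i) / Σ_j (S_j / T_j).

On top of the profiles it implements the standard two-group battery:
Chao1/Shannon/Simpson, Jaccard/Bray–Curtis/Euclidean PCoA, per-taxon
Wilcoxon tests with BH q-values, Spearman co-occurrence, LEfSe-style LDA
effect sizes (threshold 2.0), and random-forest marker selection with a
cross-validation error curve, per-sample probability of disease (POD) and
ROC/AUC.  A synthetic-data module generates genomes, two-group communities
and read sets with known ground truth, so the whole pipeline is testable
end to end.

## Worked example

Run the bundled reference study — 12 synthetic species, 10 + 10 samples
(groups M and H) with three planted effects, 20,000 reads per sample with
5% host and 10% junk contamination:

```bash
twobrad all --out run --seed 0
```

or step by step via the numbered drivers:

```bash
python analysis/01_simulate_study.py      # genomes, cohort FASTQs, truth
python analysis/02_build_marker_db.py     # in-silico digestion + markers
python analysis/03_profile_samples.py     # QC funnel, G filter, abundances
python analysis/04_diversity.py           # alpha/beta diversity, PCoA
python analysis/05_differential_abundance.py
python analysis/06_lefse.py
python analysis/07_random_forest.py
```

The drivers print their findings and write tables under `results/`.  On
the default seed:

```
markers: 335 across 12 species (digest 719441d14b06)
recovery vs ground truth over 12 species: max |error| = 0.0098, mean |error| = 0.0015
species rank: 4 of 12 taxa at p < 0.05
      taxon  mean_M  mean_H      p      q direction
GenusA_sp01 22.4218  2.9564 0.0002 0.0007         M
GenusB_sp02  2.5133 14.1312 0.0002 0.0007         H
GenusC_sp03  2.8934 11.4713 0.0002 0.0007         H
GenusC_sp09 10.4133  7.9866 0.0058 0.0174         M
4 discriminative features at LDA score >= 2.0
CV error curve minimum 0.000 at set size 1; selected: ['GenusA_sp01']
POD medians: M = 1.000, H = 0.000 (permutation p = 0.005)
cross-validated AUC = 1.000
```

Reading this: every species' relative abundance is recovered to within
0.0098 of the simulated truth; the Wilcoxon screen finds exactly the three
planted effects (plus `GenusC_sp09`, a real compositional echo of the
planted shifts — relative abundances must sum to 1); LEfSe reports the
same taxa with log10 effect sizes ~4–5; and the forest needs a single
species (`GenusA_sp01`, the M-enriched one) to separate the groups
perfectly, with POD saturated at 1 vs 0 and a permutation-calibrated
group-difference p of 0.005.

`docs/methods.md` documents the model, the G-score and POD calibration
choices, and what the synthetic tests do and do not demonstrate.

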
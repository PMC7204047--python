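# paleogut

Simulation, damage-based authentication and ecological analysis of
ancient-DNA gut metagenomes.

Shotgun sequencing of palaeo-faecal material (coprolites, desiccated
stool) can recover the taxonomic composition and metabolic capacity of
ancient intestinal microbiomes — but only after separating genuinely
ancient molecules from modern and laboratory contamination.  The
diagnostic signal is post-mortem cytosine deamination: an excess of C→T
substitutions at 5' read starts (with mirrored G→A at 3' ends in
double-stranded libraries) that decays over the first ~25 bp, combined
with short fragment lengths.  `paleogut` implements that whole workflow
as a tested Python library for researchers in ancient metagenomics and
microbiome ecology:

* **Simulation with truth** — reference panels, communities, and damaged
  short reads under the overhang-persistence model
  `d(i) = δ_ss q^i + δ_ds (1 − q^i)` for the C→T probability at distance
  `i` from the 5' end, plus sequencing error and an undamaged
  modern-contaminant fraction; every read's origin and damage events are
  recorded.
* **Pre-processing** — adapter trimming, length ≥ 25 bp, mean Phred ≥ 25,
  trinucleotide-entropy complexity ≥ 0.45, exact dedup and
  negative-control (E-LPC) subtraction, with conserving accounting.
* **Taxonomic assignment** — a k-mer seed-and-extend aligner with
  MEGAN-style reduction (identity ≥ 97%, top-percent 10, min support 10,
  lowest common ancestor), producing taxon × sample count tables.
* **Damage profiling and authentication** — positional misincorporation
  profiles; an exact one-sided binomial test of terminal C→T excess
  against an interior-window null; maximum-likelihood damage-parameter
  estimation; and a five-criterion framework (C→T significance, G→A
  support, control comparison, read length, ecological conformity) that
  classifies each taxon as `AUTHENTICATED_ANCIENT`,
  `ENVIRONMENTAL_ANCIENT`, `NOT_AUTHENTICATED` or `CONTAMINANT`.
* **Ecology / functional / resistome statistics** — relative abundance,
  F/B ratio and enterotype, rarefaction, prevalence filtering, Hellinger
  transform, Bray–Curtis (weighted and presence/absence), PCoA, ANOSIM
  with permutation p-values, Spearman-distance clustering, taxon-linked
  KO tables with Kruskal–Wallis + BH-FDR group tests and Venn
  intersections, and coverage-threshold (80% gene fraction) ARG calls.

The package ships the published read-count tables of a mid-15th-century
South African palaeo-faecal specimen (24 authenticated commensal and 12
pathogenic gut taxa) as fixtures and reproduces every statistic they
imply.

## Worked example

```python
import paleogut as pg

panel = pg.build_reference_panel(n_taxa=4, seed=7, gc=0.5, length=8000)
spec = pg.CommunitySpec("demo", "faecal_interior",
                        {t: 0.25 for t in panel.taxon_ids}, depth=5000)
params = pg.DamageParams(delta_ss=0.4, delta_ds=0.01, q=0.6, epsilon=0.001)
reads, truth = pg.simulate_sample(panel, spec, params, seed=1)

profile = pg.misincorporation_profile(pg.truth_alignments(panel, reads, truth))
test = pg.ct_terminal_test(profile)
fit = pg.fit_damage_model(profile)
```

prints (via `python examples/01_simulate_and_profile_damage.py`):

```
reads simulated:        5000
terminal C->T rate:     0.236 (interior null 0.0128)
terminal-test p-value:  4.07e-270
fitted delta_ss / q:    0.377 / 0.597 (truth 0.4 / 0.6)
```

The terminal C→T rate (≈ δ_ss·q + δ_ds·(1−q) + ε/3 ≈ 0.25) towers over
the interior null rate, the exact binomial test rejects the no-damage
null decisively, and the likelihood fit recovers the simulation
parameters to within sampling error — the quantitative signature used to
authenticate taxa as ancient.

Recomputing the published table statistics
(`python examples/03_study_table_statistics.py`):

```
phylum relative abundance (% of interior total):
  Proteobacteria   41.73
  Bacteroidetes    31.25
  Firmicutes       13.44
  Actinobacteria    8.89
  Euryarchaeota     4.68
...
F/B ratio: 0.4
enterotype: 1 (Bacteroides 22.36%, Prevotella 0.63%, Ruminococcus 1.57%)
all 19 derived statistics match the printed values: True
```

More narrative scripts live in `examples/` (authentication on a
known-truth community, cohort ecology statistics, the full demo
pipeline).  The pipeline is also exposed as a thin CLI:

```bash
paleogut run-all --outdir run --seed 0   # simulate → … → resistome
paleogut check-tables                    # verify the packaged tables
```

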
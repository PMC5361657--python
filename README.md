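# ffpm — phenotype-microarray comparison of infected vs cured fungal strains

`ffpm` analyses Biolog FF filamentous-fungus phenotype microarrays to ask
whether an endohyphal bacterium changes which carbon sources its host fungus
can use, and how well. The motivating system is a seed-associated
*Fusarium keratoplasticum* strain that naturally hosts a *Chitinophaga* sp.
(Bacteroidetes) endosymbiont: the naturally infected clone (**EHB+**) and its
antibiotic-cured clone (**EHB−**) are grown on the same 95 carbon sources
(plus a water control) on five replicate plates each, and read at two
wavelengths every 12 h for 7 days.

The package is aimed at microbial phenomics work generally: any two-condition
kinetic plate experiment with this design can be processed with it.

## What it computes

**Two-channel kinetics.** Reads at 490 nm track respiration through
irreversible formazan accumulation; reads at 750 nm track turbidity (hyphal
density). Because hyaline mycelium absorbs evenly across this range, the
corrected respiration signal is *A*<sub>c490</sub> = *A*<sub>490</sub> −
*A*<sub>750</sub>. Growth on a substrate is *measurable* when the day-7
replicate-mean turbidity satisfies 0.3 < *Ā*<sub>750,7</sub> ≤ 3.0 (strict
lower, inclusive upper bound).

**Per-substrate inference.** For each substrate the day-7 turbidity means are
compared between strains with a two-sided Welch *t*-test
(*t* = |*m*₁ − *m*₂| / √(*s*₁²/*n*₁ + *s*₂²/*n*₂), Welch–Satterthwaite df),
with Benjamini–Hochberg FDR control across all substrates on which at least
one strain grew measurably. Each substrate is then classified into five
outcomes: (1) negligible growth by both strains, (2) measurable by both with
no significant difference, (3) measurable by the EHB+ strain only, (4) the
EHB− strain denser, (5) the EHB+ strain denser. A rule-based census turns the
classification into headline counts and whole-percent shares of 95.

**Global profile statistics.** At every time point the ten replicate plates
are compared as points in 95-dimensional substrate space via the Bray–Curtis
dissimilarity Σ|*x* − *y*| / Σ(*x* + *y*), and tested for a strain effect
with three permutation procedures implemented from first principles:
PERMANOVA (pseudo-*F* and *R*² on squared-distance sums), ANOSIM (Clarke's
rank statistic *R* ∈ [−1, 1]) and MRPP (chance-corrected within-group
agreement *A*), each with *n* = 1,000 label permutations by default and exact
enumeration available for small designs. UPGMA dendrograms in Newick format
visualise the clustering of plates.

**Synthetic experiments.** A seeded generator plants per-substrate outcome
archetypes as logistic growth curves (baseline + *K* / (1 + e^(−*r*(*t* −
*t*₀)))) observed through truncated Gaussian noise, with a monotone redox
coupling, so the entire pipeline is testable end to end without any
downloaded data.

## Worked example

The package ships a transcription of the published day-7 endpoint table for
the *F. keratoplasticum* experiment. The rule-based census of that table:

```bash
$ ffpm census
{
  "n_substrates": 95,
  "used_plus": 79,
  "used_minus": 77,
  "n_significant": 64,
  "n_plus_higher": 59,
  "n_minus_higher": 5,
  "n_no_difference": 15,
  "n_plus_only": 2,
  "n_negligible_both": 16,
  "pct_plus_higher": 62,
  "pct_minus_higher": 5,
  "pct_significant": 67,
  ...
}
```

Reading: the infected strain used 79 of 95 carbon sources and the cured
strain 77; growth differed significantly on 64 substrates (67%), with the
infected strain denser on 59 (62%) and the cured strain denser on 5 (5%);
on 2 substrates only the infected strain grew at all; 15 substrates were
used equally and 16 supported negligible growth by both.

A fully synthetic experiment, simulated and analysed in one call:

```bash
$ ffpm run --simulate --out demo --seed 7 --n-perm 199
artifacts in demo
$ head -4 demo/global_scan.tsv
day	permanova_F	permanova_R2	permanova_p	anosim_R	anosim_p	mrpp_A	mrpp_p
0.5	1.124	0.1231	0.21	0.132	0.135	0.007938	0.205
1	1.339	0.1434	0.05	0.3	0.035	0.01626	0.05
1.5	1.199	0.1304	0.165	0.12	0.19	0.009825	0.165
```

Early in the run the strains are indistinguishable (*R*² ≈ 0.12, *p* > 0.05);
as planted effects emerge in log/stationary phase the scan's *R*² climbs
above 0.95 with *p* at the permutation floor by day 7. `demo/` also contains
the endpoint summary table (`summary.tsv`), the census (`census.json`), a
day-7 UPGMA dendrogram (`dendrogram_day7.nwk`) and the planted truth for
comparison.

The same analyses are available as library functions
(`ffpm.summarize_substrates`, `ffpm.census`, `ffpm.global_scan`,
`ffpm.permanova`, ...).

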
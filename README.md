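# domgen

Population-genetic analysis for **dominant molecular markers** — band
presence/absence (0/1) matrices scored from ISSR, SCoT, EST-SSR, RAPD or
AFLP assays, where a band's absence is the recessive homozygote and
heterozygotes are invisible. It is aimed at plant-germplasm surveys of the
classic kind: a few dozen primers amplified across one-to-a-few hundred
accessions, and the questions "how diverse is this collection, which marker
system earns its lanes, how is the collection structured, and is there
enough linkage disequilibrium for association mapping?"

One package covers the full workflow:

- **Diversity** — TNB / NPB / PPB per primer and marker type; Nei's gene
  diversity *H* = 2pq and Shannon's *I* = −p ln p − q ln q on HWE
  square-root allele-frequency estimates (Lynch–Milligan correction
  optional).
- **Marker efficiency** — band informativeness Ib = 1 − 2|0.5 − p|, its
  average Ib_av, effective multiplex ratio EMR (mean polymorphic bands per
  primer) and marker index MI = EMR · Ib_av.
- **Distances & ordination** — Nei–Li (Dice) similarity 2a/(2a+b+c),
  modified Rogers distance √(Hamming/L), UPGMA dendrograms with
  locus-bootstrap (Felsenstein) support and Newick export, Gower PCoA via
  double-centering.
- **AMOVA** — Excoffier two-level variance partitioning among/within groups
  on squared Euclidean band distances, Φ_ST, label-permutation p-values.
- **Population structure** — Bernoulli-observation Bayesian admixture model
  fitted by Gibbs sampling over a K grid, LnP(D) evidence, Evanno ΔK model
  selection, and 0.75-membership subpopulation assignment.
- **Linkage disequilibrium** — all-pairs r² between binary loci after MAF
  filtering, chi-square (X² = n·r²) or permutation significance, and
  subpopulation-stratified summaries.
- **Synthetic data** — a Balding–Nichols generator with HWE dominance
  collapse, configurable admixture and block-copy LD injection, shaped by
  default like a 134-accession, 51-primer, two-ecotype collection.

See `docs/methods.md` for the models and numerical conventions.

## Worked example

Marker-efficiency scoring of the packaged 51-primer reference survey
(16 ISSR, 20 SCoT, 15 EST-SSR primers; per-primer band counts shipped in
`src/domgen/data/primer_band_counts.tsv`):

```sh
$ domgen efficiency
  scope  n_primers  TNB  NPB     PPB  mean_bands_per_primer     EMR  Ib_av     MI  EMR_2dp  MI_2dp
   ISSR         16  220  196 89.0909                13.7500 12.2500 0.3800 4.6550  12.2500  4.6600
   SCoT         20  445  402 90.3371                22.2500 20.1000 0.4300 8.6430  20.1000  8.6400
EST-SSR         15  128  110 85.9375                 8.5333  7.3333 0.3600 2.6400   7.3300  2.6400
```

The three systems together yield 793 bands of which 708 (89.28 %) are
polymorphic. SCoT's EMR of 20.10 polymorphic bands per primer — roughly
twice ISSR's 12.25 and almost three times EST-SSR's 7.33 — drives its
marker index of 8.64, making it the most efficient assay per lane even
though the per-band informativeness (Ib_av 0.36–0.43) barely differs
between systems.

Simulating a structured collection and partitioning its variance:

```python
from domgen import SimConfig, simulate_dataset
from domgen.distances import euclidean_squared_matrix
from domgen.amova import amova

m, meta, truth = simulate_dataset(SimConfig(seed=1))   # 134 x 811 bands
d = euclidean_squared_matrix(m)
res = amova(d, truth.origin, n_perm=999, seed=1)
print(f"among {res.pct_among:.2f}%  within {res.pct_within:.2f}%  "
      f"Phi_ST {res.phi_st:.3f}  p {res.p_value:.3f}")
```

```
among 32.87%  within 67.13%  Phi_ST 0.329  p 0.001
```

About a third of band-profile variance lies between the two latent
subpopulations at the generator's default differentiation (F = 0.35), and
no label permutation out of 999 reaches the observed Φ_ST.

The full pipeline (diversity → efficiency → tree → PCoA → AMOVA →
structure/ΔK → stratified LD) runs from one command:

```sh
domgen run --seed 42 --out results/
domgen structure band_matrix.tsv --kmin 1 --kmax 5 --reps 5 --seed 3 --out runs/
```

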
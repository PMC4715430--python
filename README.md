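# codiv — community co-diversification analysis for amplicon surveys

`codiv` asks a comparative-phylogeography question at the scale of a whole
community: when many taxa live together in one habitat patchwork split by a
biogeographic barrier, do **more of them share population-genetic structure
across that barrier than chance would predict?** The motivating system is the
inquiline community of the pitcher plant *Sarracenia alata* — fungi, mites,
nematodes, insects and protists sampled directly from pitcher fluid with a
~275 bp 28S amplicon — distributed across five collection locales, two west
and three east of the Mississippi River.

The pipeline goes from demultiplexed per-sample FASTA to a community report:

1. **OTU assembly** — trim reads to a fixed length, collapse identical reads
   (dereplication with abundances), greedy abundance-sorted clustering at 97%
   global-alignment identity with a single-crossover chimera screen, and a
   comparative filter (≥ 10 sequences per OTU, ≥ 3 on each side of the
   barrier).
2. **Per-OTU statistics** — center-star multiple alignment (or an external
   aligned FASTA), then for every OTU:
   * diversity: segregating sites *S*, mean pairwise differences *k̂*,
     nucleotide diversity π, Watterson's θ<sub>W</sub> = S/(a₁L);
   * Tajima's *D* = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)), tested against the
     classical rescaled-beta null (a coalescent simulation null is also
     available);
   * haplotype G<sub>ST</sub> = (H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub>
     (Nei–Chesser small-sample corrections) with a permutation test;
   * hierarchical AMOVA on squared pairwise distances with variance
     components σ²<sub>a</sub>, σ²<sub>b</sub>, σ²<sub>c</sub> and
     Φ<sub>CT</sub>, Φ<sub>SC</sub>, Φ<sub>ST</sub>, each with its own
     permutation scheme;
   * the genealogical sorting index (GSI) of each region on a
     neighbor-joining K2P genealogy (0 = no sorting, 1 = monophyly);
   * a one-tailed Mantel test of locale-mean K2P distance against
     great-circle geographic distance (isolation by distance).
3. **Community synthesis** — per-test counts of significant OTUs and a 1-df
   chi-squared goodness-of-fit against the α·N expected under the null of no
   shared structure, group aggregates, rarefaction curves, and TSV/JSON
   reports.

A structured-coalescent simulator (built on msprime) generates whole
communities with known ground truth — five demes split two/three across a
barrier, heavy log-series OTU-abundance skew, and a configurable mixture of
barrier-structured and panmictic OTUs — and is used for the calibration and
power tests.

## Worked example

```python
from codiv import PipelineConfig, geo_distances, run_pipeline
from codiv.simulate import SimulationConfig, simulate_community

data = simulate_community(
    SimulationConfig(n_otus=8, seed=42, abundance_range=(14, 120), logseries_p=0.99)
).write("demo/data")

config = PipelineConfig(seed=7, n_permutations=999)
geo = geo_distances({
    "K": (31.0, -92.9), "C": (30.8, -92.7),
    "L": (30.5, -90.2), "A": (30.5, -90.0), "T": (30.4, -89.9),
})
manifest = run_pipeline(data["reads"], data["samples"], config, "demo/run", geo=geo)
print(manifest.counts)
```

```
{'reads_in': 448, 'after_trim': 448, 'after_month_filter': 448, 'uniques': 114,
 'otus': 13, 'chimera_discarded_reads': 0, 'comparative_otus': 9, 'dropped': 4}
```

The simulated community here contains 4 barrier-structured and 4 panmictic
OTUs; clustering recovers 13 OTUs (deep coalescent clades can split an OTU) of
which 9 pass the comparative filter. `demo/run/community_table.tsv` then holds
one row per OTU (excerpt):

```
 otu_id  size       pi  tajimas_d    phi_st  p_phi_st       gst  p_gst  gsi_east  p_gsi_east
      0    51 0.000428  -1.693970  0.036854     0.381 -0.028372  0.925  0.000000       1.000
      2    48 0.009878  -1.375120  0.472807     0.001  0.127327  0.036  0.865497       0.001
      6    73 0.015546  -0.296328  0.293943     0.001  0.099755  0.001  0.541935       0.001
      4    57 0.012582   0.191196 -0.061666     0.817 -0.074071  0.999  0.000000       1.000
```

The structured OTUs (rows 2 and 6 above) show high Φ<sub>ST</sub>, significant
G<sub>ST</sub> and strong allelic sorting (GSI) on the eastern side of the
barrier, while the panmictic OTUs (rows 0 and 4) do not. The synthesis table
(`gof_tests.tsv`) asks whether 4 of 9 significant OTUs is more than the 5%
expected by chance:

```
    test      chi2      p_value  observed_significant  total
  phi_st 29.479500 5.651030e-08                     4      9
  phi_ct  0.473684 4.912970e-01                     0      9
     gst 29.479500 5.651030e-08                     4      9
gsi_east 29.479500 5.651030e-08                     4      9
  mantel  0.707602 4.002410e-01                     1      9
```

— strong community-level evidence of shared structure for Φ<sub>ST</sub>,
G<sub>ST</sub> and GSI, none for isolation by distance in this simulation.

The same pipeline runs from the shell:

```bash
codiv simulate --out demo/data --seed 42 --n-otus 8
codiv run-all --fasta demo/data/reads.fasta --samples demo/data/samples.tsv \
    --out demo/run --seed 7 --permutations 999 --coords coords.tsv
```

with stagewise subcommands (`cluster`, `filter`, `align`, `stats`,
`community`) that compose to exactly the same output.

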
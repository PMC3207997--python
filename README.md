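# retex — repeat-element expression against a uniform-transcription null

Roughly half of a mammalian genome is repeat-derived (Alu and other SINEs,
LINE-1/LINE-2, endogenous retroviruses, DNA transposons, satellites), and a
substantial share of the reads in a bulk RNA-seq library originates from these
elements. The question this package addresses is whether that expression is
just promiscuous background transcription — in which case the reads assigned
to each repeat family should mirror the fraction of repeat sequence space the
family occupies — or element-specific regulation, in which case some families
will be systematically over- or under-represented relative to that
expectation.

`retex` implements the full analysis for transcriptomics researchers working
at desk scale (toy or subsampled genomes):

1. **Reference construction** — every annotated repeat instance is extracted
   from the genome with a 50 bp flank of unique sequence on each side, so
   junction-spanning reads still align; entries carry a family label from a
   configurable taxonomy (12 labels by default).
2. **Alignment** — a seed-and-extend short-read aligner with the policy used
   for repeat quantification: zero mismatches in the first 20 read bases,
   ungapped extension up to a mismatch cap, exactly one best alignment kept
   per read (deterministic tie-break), both strands searched. Counts
   accumulate per family, not per locus.
3. **Null simulation** — the random-transcription hypothesis is
   operationalized directly: many independent datasets of 76 bp reads are
   extracted verbatim at uniform start positions over the repeat database
   (or, alternatively, over a coding-sequence database) and pushed through
   the *same* aligner, so alignment biases cancel between conditions.
4. **Testing** — per family, observed versus simulated counts are compared
   with a negative-binomial exact test: with median-of-ratios size factors
   `s_j`, pooled per-unit mean `q₀`, and per-condition raw variance `v(q)`
   (method-of-moments, isotonically pooled across families, floored at shot
   noise), the condition sums are modeled as `K_A ~ NB(μ_A = q₀·Σs_j,
   σ²_A = μ_A + v(q₀)·Σs_j²)` and the two-sided p-value sums the
   probabilities of all splits `a + b = k_A + k_B` no more likely than the
   observed one. P-values are Benjamini–Hochberg corrected across families;
   everything is computed in log space so the astronomically small p-values
   that arise at sequencing depth survive underflow.
5. **L1 5' profiling** — reads assigned to the L1 family are realigned with a
   gapped Smith–Waterman aligner to a panel of full-length L1 consensus
   sequences; each read's start coordinate is averaged over its
   per-consensus best hits and histogrammed against the simulated null.
   Because most genomic L1 copies are 5'-truncated and only full-length
   copies carry the internal promoter, an excess of observed mass in the
   5'-most bins is the signature of promoter-driven full-length expression.
6. **Synthetic data** — a generator plants truth-tracked repeat copies
   (with per-family divergence and L1-style 5' truncation), genes with
   log-normal expression, and read mixtures with per-family expression
   multipliers, so the whole pipeline is testable end to end without
   downloads.

## Worked example

Plant a 2× overexpressed Alu-like family in a synthetic genome, align ten
samples and twenty simulated null datasets, and test:

```python
import retex as rx

syn = rx.make_genome(rx.SyntheticGenomeConfig(rng_seed=1, embedded_repeat_fraction=0.0))
db = rx.build_repeat_db(syn.genome, syn.annotations)     # 50 bp flanks
index = rx.SeedIndex(db)
cfg = rx.AlignerConfig()                                 # exact 20 bp seed, <= 3 mismatches
fams = list(syn.taxonomy)

expr = rx.ExpressionConfig(n_reads=2000, multipliers={"Alu_SINE": 2.0}, rng_seed=5)
cols = []
for s in range(10):
    reads, _ = rx.make_reads(syn, expr, sample_seed=100 + s, id_prefix=f"s{s}")
    table, _ = rx.align_batch(reads, index, cfg)
    cols.append(rx.count_by_family(table, fams, f"s{s}"))
observed = rx.assemble_matrix(cols, "observed")

null = rx.null_counts(db, rx.NullConfig(n_datasets=20, reads_per_dataset=2000, rng_seed=11),
                      index, cfg, fams)
res = rx.run_table1(observed, null)
print(res[["fold_change", "p_raw", "p_adj"]].to_string(float_format=lambda x: f"{x:.3g}"))
```

```
           fold_change     p_raw     p_adj
family
Alu_SINE         0.535 8.24e-132 9.89e-131
L1                1.02     0.492     0.633
L2                 1.1    0.0795     0.477
ERV               1.06     0.281     0.633
LTR              0.971     0.633     0.633
TcMar            0.928     0.227     0.633
hAT               1.07     0.338     0.633
DNA              0.965      0.59     0.633
CR1               1.07     0.391     0.633
Satellite        0.912     0.167     0.633
MIR               1.04     0.589     0.633
Other            1.08      0.454     0.633
```

Fold change is oriented simulated/observed, so an overexpressed family sits
*below* 1: the planted Alu doubling is recovered at fold change ≈ 0.54 with
an adjusted p-value of ~1e-130, while the eleven unperturbed families are
null. The same pipeline is available as a shell tool (`retex build-db`,
`retex align`, `retex simulate-null`, `retex test`, `retex l1-profile`,
`retex synth genome/reads`, or `retex run --config run.yaml` for the whole
orchestrated run with manifest and caching).

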
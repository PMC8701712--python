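# rdnanet

NET-seq analysis of RNA polymerase I occupancy on the yeast rDNA repeat.

In *Saccharomyces cerevisiae*, Pol I transcribes the 35S pre-rRNA gene and
is supposed to terminate at a primary terminator (T1, 91 bp downstream of
the mature 25S rRNA 3′ end) with a downstream failsafe (T2).
Native elongating transcript sequencing (NET-seq) captures the nascent RNA
still held by the polymerase, so the 5′ end of each mapped read reports the
polymerase active site at single-nucleotide resolution.  Comparing a
wild-type strain with a termination-deficient mutant (such as a deletion of
the A12.2/Rpa12 subunit) then reveals where polymerases redistribute: along
the 35S body, past the terminators, through the intergenic spacers (IGS 1,
the Pol III-transcribed 5S gene, IGS 2) and up to a putative
promoter-proximal pause/termination site (Tp) just upstream of the Reb1
binding site, 215 bp before the next repeat's transcription start site.

`rdnanet` implements that analysis as a reusable library and CLI:

- **annotation** — coordinate frames (35S TSS, mature 25S end, downstream
  TSS) and features of one rDNA repeat, with BED6/JSON I/O.
- **occupancy** — strand-aware 5′ read-end counting from SAM/BAM,
  bedGraph I/O, normalization to the 35S-body sum (positions 1..T1 = 6739),
  replicate aggregation by per-position median.
- **reproducibility** — pairwise Spearman rank correlation of replicates.
- **differential** — per-position Student/Welch t-tests between strains
  (two-sided, α = 0.05, raw p by default, Benjamini–Hochberg optional) and
  a 300-nt centred moving average.
- **seqcontext** — top-2.5% occupied positions, last-incorporated-
  nucleotide (LNT)-anchored sequence contexts, and a difference logo:
  per-column Jensen–Shannon divergence (bits) with signed per-symbol
  contributions and permutation p-values.
- **termination** — terminator read-through index
  (downstream/upstream mean occupancy; efficiency = 1 − index) and robust
  (median/MAD) pause-cluster detection.
- **simulate** — a generative model (sequence-dependent dwell, pause
  folds, memoryless terminator survival, negative-binomial replicate
  noise) so every stage can be validated against known ground truth.
- **pipeline / cli** — one-command end-to-end runs with a results
  directory and a reproducible manifest.

## Worked example

Simulate a wild type and a termination-deficient mutant (10⁶ expected
reads per replicate, three replicates each) and run the core analyses:

```python
import rdnanet as rn

ann = rn.default_annotation()
truth = rn.example_truth(ann, seed=0, depth=1_000_000)
ds = rn.simulate_occupancy(truth, ann)

norm = {s: [rn.normalize_35S(p, ann) for p in ds.replicates(s)]
        for s in ds.strains}
for s in ds.strains:
    rho = rn.spearman_matrix(norm[s], ann=ann).min_offdiagonal()
    print(f"{s}: min replicate Spearman rho = {rho:.3f}")

med = {s: rn.median_profile(norm[s]) for s in ds.strains}
track = rn.positionwise_test(norm["WT"], norm["mutant"],
                             region=(1, ann.position("T1")))
print("up in mutant:", len(track.positions_called("up")),
      "down:", len(track.positions_called("down")))

for s in ds.strains:
    m = rn.terminator_metrics(med[s], ann, "T1")
    print(f"T1 read-through ({s}): {m.readthrough_index:.3f} "
          f"efficiency {m.efficiency:.3f}")

c = rn.detect_pause_clusters(med["mutant"], "IGS2", ann=ann)[0]
print(f"top IGS2 pause: {c.distance_upstream_of_downstream_tss} bp "
      "upstream of the next 35S TSS")
```

Output:

```
WT: min replicate Spearman rho = 0.964
mutant: min replicate Spearman rho = 0.959
up in mutant: 161 down: 185
T1 read-through (WT): 0.089 efficiency 0.911
T1 read-through (mutant): 0.702 efficiency 0.298
top IGS2 pause: 215 bp upstream of the next 35S TSS
```

Replicates agree (ρ > 0.95); the wild type terminates efficiently at T1
while the mutant reads through (efficiency 0.30 versus the generative
read-through setting of e_T1 = 0.2, biased by sequence-dependent dwell —
see `docs/methods.md`); and the mutant's injected Tp pause is recovered as
the top IGS 2 cluster exactly 215 bp upstream of the downstream TSS.

The same analyses are available from the shell:

```sh
rdnanet simulate --out sim/ --seed 0 --sam
rdnanet run-all --out results/ --seed 0
rdnanet occupancy sim/mutant_rep1.sam --out mutant_rep1.bedgraph
```

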
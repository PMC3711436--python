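# mitobait

Reconstruction of complete circular mitochondrial genomes directly from
whole-genome shotgun reads, by **k-mer baiting and iterative mapping** —
for anyone who has NGS reads of a non-model organism but no conspecific
mitochondrial reference. A distantly related mitogenome, or even a short
COI barcode (~650 bp), is enough to seed the process; no long-range PCR,
no whole-genome de-novo assembly.

## How it works

Starting from the seed reference *R₀*, each iteration *t*:

1. **bait** — recruit from the *full* read pool every read sharing ≥ *n*
   exact canonical k-mers with *Rₜ* (defaults k = 31, n = 1). The long
   exact k-mer is what makes the pipeline specific.
2. **map & extend** — place recruited reads on *Rₜ* by tolerant overlap
   alignment: accept a read iff its mismatches (substitutions + indel
   bases) are ≤ 15% of the alignment-overlap columns, and any read
   overhanging a contig end overlaps it by ≥ 30 bases. *Rₜ₊₁* is the
   per-column majority consensus of the placed reads (the old reference
   never votes); accepted overhangs grow the ends, uncovered columns
   split the reference into contigs.
3. repeat until the recruited-read count (and reference length) are
   stationary; terminal self-overlap ≥ 100 bp is trimmed and the contig
   flagged circular.

Two further modes: a **de-novo mode** (greedy reassembly of the recruited
pool each iteration, with mate rescue — extension per iteration reaches
insert-size range, converging in several-fold fewer iterations) and a
**proofreading mode** for pooled/mixed samples, which admits a read pair
only if one mate matches the trusted reference at 100% identity over its
full length, and commits extension columns only on unanimous evidence —
so each species' genome can be fished cleanly out of a mixed pool from
its own barcode. The package also includes the paired-read simulator used
for benchmarking and an evaluation harness (assembly scoring, recruitment
metrics, k-mer-spectrum genome-size and copy-number estimates).

## Worked example

Simulate a 16.6 kb mitogenome-like sequence, 6000 error-free 150 bp
paired reads (~54×), and rebuild the genome from a 650 bp barcode:

```bash
mitobait simulate-genome --length 16600 --at-content 0.55 --seed 11 --out mt.fasta
mitobait simulate-reads --genome mt.fasta --n-reads 6000 --seed 12 --out reads.fastq
# seed.fasta = any ~650 bp slice of mt.fasta (a COI-barcode stand-in)
mitobait run --reads reads.fastq --interleaved --seed seed.fasta --outdir out
```

which prints

```
converged=True iterations=71 contigs=1 total_length=16600 recruited=6000
```

— the loop converged after 71 iterations with a single 16 600 bp contig
(`out/final.fasta`, header `circular=true mean_cov=54.2`) and all 6000
reads recruited. Scoring against the simulated truth:

```bash
mitobait evaluate --assembly out/final.fasta --truth mt.fasta --circular
# seed   0/0 (100.00%)   length=100.00%
```

`0/0 (100.00%)` is the conventional report form: substitutions/indels
(percent identity) after rotating the circular truth to the assembly —
here a perfect reconstruction of the full length. The k-mer spectrum of
the read set estimates the genome size without any assembly:

```bash
mitobait kmerspec --reads reads.fastq
# peak_cov=44  genome_size_est=17864
```

(total above-noise 20-mer instances divided by the coverage peak; the
mode of the discrete histogram wobbles a few units around the true k-mer
coverage, so single-run estimates land within a few percent of the truth).
`out/iterations.tsv` traces the growth, e.g. `1  249  878` →
`71  6000  16600`: recruited reads and reference length per iteration.

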
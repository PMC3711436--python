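# Methods

## The reconstruction model

`mitobait` reconstructs a complete circular mitochondrial genome from a
whole-genome shotgun read pool without a conspecific reference. The key
observation is that mitochondrial reads are hugely over-represented in
total-DNA libraries (often a ~130-fold copy-number excess over nuclear
sequence), so a tiny trusted seed — a related species' mitogenome, or a
~650–1200 bp COI barcode — suffices to nucleate an iterative
seed-and-extend process over the *whole* pool:

1. **Baiting.** All reads sharing at least *n* exact canonical k-mers
   (defaults k = 31, n = 1) with the current reference are recruited from
   the full original pool. Long exact k-mers carry the specificity of the
   whole pipeline: the subsequent mapping is deliberately permissive, so
   recruitment, not alignment stringency, is what keeps foreign reads out.
   Canonical (strand-minimum) k-mers make matching strand-symmetric;
   windows containing N are skipped because an exact match cannot pass
   through an ambiguous base.
2. **Mapping and consensus.** Recruited reads are placed by
   seed-and-extend: exact k-mer anchors propose diagonals (every baited
   read has one by construction), verified by direct comparison or a
   windowed edit-distance alignment. A placement is accepted iff
   (a) mismatches — substitutions plus inserted/deleted bases — occupy at
   most 15% of the alignment-overlap columns, and (b) a read that
   overhangs a contig end overlaps it by at least 30 bases. The new
   reference is the per-column majority vote over placed read bases; the
   previous reference never votes, so distant-reference sequence cannot
   leak into the consensus. Uncovered columns are excised and split the
   contig (the reference may be gapped early on); accepted overhangs
   extend contigs outward by up to read-length − 30 per end per iteration.
3. **Convergence.** Steps 1–2 repeat until the recruited-read count and
   the total reference length are both unchanged across
   `convergence_window` (default 1) successive iterations, or
   `max_iterations` (default 200) is reached. Because baiting always runs
   against the full original pool and results accumulate by union, the
   count is non-decreasing and bounded by the pool size, so termination is
   guaranteed. Length stationarity is included because in proofreading
   mode the reference can grow for one iteration without the count moving
   (a pending mate becoming placeable); counts alone can stop a step early.

A linear assembly of a circular genome accumulates a duplicated terminal
overlap; once a suffix of ≥ 100 bp matches the prefix at ≥ 95% identity
the duplicate is trimmed and the contig flagged circular. Subsequent
placements treat the contig modulo its length, so origin-spanning reads
are recovered.

### De-novo verification mode

Instead of mapping, the recruited pool (optionally widened by the mates of
all baited reads, `pair_rescue`) can be assembled from scratch each
iteration by a small greedy overlap-layout-consensus assembler: repeatedly
merge the highest-scoring ungapped suffix–prefix overlap (score =
overlap − 2·mismatches, minimum 30 bases), both orientations considered,
contained sequences absorbed, coverage-weighted majority at mismatching
columns. Because mates reach up to an insert length beyond the current
contig, extension per iteration reaches insert-size range and convergence
takes several-fold fewer iterations than mapping mode (observed 7 vs 20 on
the 3 kb test genome; the same several-fold gap the mapping-vs-denovo
comparison shows at full scale). Candidate overlaps are seeded by an exact
prefix gram of g = min(20, min_overlap) bases, so overlaps whose seed
region contains an error can be missed; this assembler is a verification
tool for (nearly) error-free recruited pools, not a general-purpose
assembler.

### Proofreading mode (pooled / mixed samples)

For read pools containing several related mitogenomes, tolerant mapping
would chimerise conserved regions. Proofreading mode (single-barcode seed,
fully paired pool) instead requires **perfect evidence**:

* a read pair is incorporated only if at least one mate matches the
  current trusted reference with 100% identity over its **entire length,
  fully interior** to the reference (the anchor);
* the other mate may overlap a reference end perfectly (≥ 30 bases) and
  overhang it — its overhang bases are extension candidates; a mate that
  overlaps the reference anywhere with a mismatch disqualifies the whole
  pair (counted as an avoided false positive);
* an extension column is committed only when **all** candidate bases
  agree; the committed region becomes trusted as a whole;
* if two conflicting extension variants are each supported by ≥ 2 reads,
  extension on that side halts permanently — this is exactly the situation
  of a conserved block shared between congeners that is longer than the
  library insert, where no pairing information can disambiguate the exit
  from the block. Shorter shared blocks are harmless: a foreign pair's
  anchor mate would have to sit entirely inside the block, i.e. the block
  would need to exceed the read length, and at ~0.13 K2P divergence
  identical runs ≥ 150 bp essentially never occur (expected count ≪ 1 per
  genome pair), while ≥ 30 bp runs are common (~40 per pair) — which is
  why a fully-interior full-read anchor is required rather than a 30 bp
  edge anchor.

A pair incorporated on a perfect anchor whose far mate becomes placeable
only later and then conflicts is recorded as a conflict event but not
un-incorporated (the recruited set stays monotone); with error-free
conspecific reads this cannot occur.

## Synthetic data: what it emulates and what it does not

`simulate` generates the benchmark conditions end to end:

* **Genomes.** i.i.d. bases with P(A) = P(T) = AT/2 (defaults 16 600 bp,
  AT 0.55, the salmonid-like composition; 0.62 reproduces the AT-rich
  flatworm-like case), optionally with a 750–800 bp non-coding tandem
  repeat. Relatives are derived by per-site substitution with equal
  transition/transversion weighting; with uniform substitution the
  expected K2P distance reduces to −(3/4)·ln(1 − 4p/3), which is inverted
  (scipy brentq) for the per-site probability p, so `divergence` is the
  expected K2P distance. Two descendants at d each sit at ≈ 2d (verified:
  0.13 + 0.13 → 0.24–0.28).
* **Reads.** Paired, read length 150 bp, insert N(300, 50²) truncated to
  ≥ read length, 6000 reads per genome (~54×), error rate 0 by default.
  Fragments start uniformly on the **circle**, so coverage is uniform and
  reads span the origin; a `linear` flag reproduces the end-coverage
  deficit of simulating from a linearised template (useful for studying
  the recovered-length artefact that produces <100% length values on
  otherwise perfect reconstructions).
* **Pooling** concatenates read sets with per-read provenance labels, the
  ground truth for recruitment/false-positive accounting.

Not emulated: platform error profiles, quality-score distributions, indel
sequencing errors, gene content, NUMTs, and host/nuclear background reads.
Passing the pooled benchmark therefore demonstrates the *specificity and
completeness of the recruitment/extension logic* under known truth — not
robustness to base-calling error (the real pipeline assumes error-corrected,
quality-trimmed input) nor performance on nuclear-contaminated pools.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k`, `n` | 31, 1 | baiting word size / count; 31 is long enough that a chance hit between 0.13-divergent genomes is rare, short enough that every 150 bp read of the target carries dozens |
| `max_mismatch_frac` | 0.15 | mapping tolerance per alignment overlap; spans ~2× the per-site divergence of a congeneric reference |
| `min_edge_overlap` | 30 | minimum anchored overlap for extending a contig end |
| `strict_frac` | 0.05 | step-one stringency when a distant reference shows spurious high-coverage similarity |
| `min_cov` | 1 | any read evidence retains a consensus column; below it the column is excised |
| circularity | 100 bp, 0.95 | terminal-duplication detection; must stay below read length (the duplication a mapping run can build is capped near read length) |
| `convergence_window` | 1 | two equal consecutive (count, length) pairs define stationarity |
| `max_iterations` | 200 | safety cap comfortably above the worst case a short-barcode mapping-mode run needs (~115 at mitogenome scale) |

## Numerical and tie-breaking choices

* Overlap alignment scores +1/−1/−2 (match/mismatch/gap); scores only rank
  candidate placements — acceptance is decided by the mismatch-fraction
  and edge rules, never by score thresholds. The full free-end-gap matrix
  is computed (numpy row recurrence with a prefix-max trick for the
  horizontal gap chain); banding is effectively provided by the anchored
  verification window (`band_width` padding around an exact anchor).
* "Mismatches" counts substitutions **plus** inserted and deleted bases
  within the overlap — the conservative reading that blocks gap-riddled
  placements.
* Placement ties: best score, then lowest contig index, lower start,
  + strand. Consensus column ties: bases beat deletion, alphabetic among
  bases (reads carry no qualities in any supported pipeline, so the
  quality-weighted refinement would be dead code). Greedy-assembler merge
  ties: longer merged contig, then lexicographic id; conflicting overlap
  columns follow the higher accumulated coverage.
* Degenerate inputs: empty FASTA/FASTQ parse to empty lists; an all-N or
  shorter-than-k reference refuses to build a bait index; a pool where no
  read places on the distant reference aborts with "seed too distant";
  proofreading refuses unpaired pools and multi-contig references;
  spectrum estimation refuses data whose coverage peak is indistinguishable
  from low-multiplicity noise (cutoff 3).

## Evaluation

`compare_assemblies` doubles the truth for circular comparison (every
rotation is then a contiguous match), tries both strands, and counts
substitutions and indel *events* (one contiguous gap = one event) from the
optimal alignment, reported in the conventional "subs/indels (identity%)"
form; identity below 50% is flagged not credible. `recruitment_metrics`
computes target-read recovery and heterospecific fraction from provenance
labels. `kmer_spectrum_stats` histograms canonical 20-mer multiplicities;
the mode above the noise cutoff estimates k-mer coverage, total above-noise
k-mer instances divided by the peak estimate genome size (within ±5% on
error-free uniform simulations), and the ratio of two pools' peaks
estimates relative organelle copy number.

## Problem sizes used by the shipped checks

The pooled benchmark runs at full scale: five 16 600 bp genomes, ~0.13
pairwise K2P, 6000 reads each (30 000 pooled), ~1200 bp seeds, five
proofreading reconstructions (~70 iterations each; a few minutes total on
one CPU, dominated by the one-off inverted k-mer index over the pool).
Unit and property tests use 1–5 kb genomes at 20–50× so the whole suite
stays fast.

## Known limitations

* Proofreading requires error-free or error-corrected reads: a single
  sequencing error in the anchor mate blocks incorporation of the pair
  (by design), so raw-error libraries lose recruitment sensitivity.
* Repeat regions longer than the read length place ambiguously; reads are
  assigned to the leftmost best position, which degrades repeat-region
  accuracy exactly as iterative mapping approaches generally do.
* The greedy assembler's exact-gram seeding misses overlaps whose first
  bases are mutated; it is a verification device, not a primary assembler.
* Shared conserved blocks longer than the library insert halt proofreading
  extension (reported, not silently bridged); a longer-insert library is
  the only remedy.
* `initial_reference` against a very distant genome relies on the
  exhaustive overlap aligner for anchor-less reads and is therefore the
  slowest path; it is intended for mitogenome-scale references.
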
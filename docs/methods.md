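# Methods

This note records the models, defaults and numerical choices behind
`cobin`, and what the synthetic-data tests do and do not demonstrate.

## Pipeline model

The pipeline treats each species as an independent assembly problem. The
premise is the three-regime behaviour of LCA read classification against a
reference database:

* reads from **species-specific** sequence classify at species rank;
* reads from **inter-species repeats** (sequence shared verbatim between
  references) collect classifier hits only at the lowest common ancestor
  of the sharing species and land above species rank;
* reads from **unique genome-specific** sequence (sample sequence absent
  from all references) collect no hits and stay unclassified.

Cobarcoding restores the latter two classes: a long fragment that spans a
repeat or a novel insertion also spans flanking species-specific sequence,
so its barcode carries species-classified reads. Collecting *whole
barcodes* ranked by their taxonomy-read content therefore recruits exactly
the reads LCA classification loses, at the price of occasional foreign
reads from barcode collisions — which the decontamination stage removes at
the contig level.

## Refinement parameters

| parameter | default | meaning |
|---|---|---|
| `cap_coverage` | 300 (fold) | stop collecting ranked barcodes once collected bases reach 300× the reference length; bounds assembler input for very abundant species |
| `min_abundance` | 10 (fold) | strict gate on the TR-based abundance estimate; shallower species cannot be assembled completely and are reported as skipped |
| `min_num_t`, `min_ratio_t` | off | optional hard floors per barcode; the ranking plus cap is the only constraint by default |
| `include_unbarcoded` | false | reads with the `0_0_0` sentinel barcode carry no cobarcoding signal and are excluded; the flag admits their TRs directly |

Semantics pinned down where prose alone is ambiguous:

* `Ratio_T`'s denominator is the barcode's read count over the **whole
  dataset**, not within one species — only then does it measure barcode
  purity. Ties in the ranking break by barcode string so results are
  order-independent; ratio comparisons use exact fractions.
* The cap is enforced **pre-inclusion**: the barcode whose inclusion first
  reaches `cap × L` is included whole, then collection stops. Barcodes are
  atomic because the cobarcoding signal is barcode-level.
* TR membership means the classification equals the species taxid exactly;
  strain-level assignments are lifted to their species ancestor while
  parsing, which makes adapter output from species-representative
  databases and the fixture classifier interchangeable.
* Abundance = total TR bases (both mates) / reference length. Repeat and
  insertion regions withhold reads from the TR set, so the estimate sits
  slightly below the true coverage — the gate is intentionally applied to
  this conservative estimate.

## Fixture classifier

A Kraken-style k-mer LCA classifier (canonical 31-mers, both mates scored
jointly) exists so the pipeline runs without external tools; the Kraken2
output parser is the production path. Each indexed k-mer maps to the LCA
of the genomes containing it. A read's candidate taxa are its hit taxa;
each candidate scores the summed hits along its root-to-candidate path,
the maximum wins, and ties break to the smallest taxid. A read whose hits
sit entirely on one ancestral node classifies at that node — the property
the refinement stage depends on. This classifier omits minimizers,
confidence scoring, and probabilistic reassignment of above-species reads.

## Synthetic communities

`cobin.simulate` generates references (i.i.d. uniform DNA), plants shared
repeat blocks copied verbatim across species pairs, then derives each
sample genome by point substitutions (default rates 0–0.2%) plus novel
random insertions (`unique_insertion_fraction` of the genome, in blocks of
~1–1.5 kb). The library model draws log-normal fragment lengths (median
30 kb, σ = 0.35), assigns each fragment a fresh barcode or — with
probability `collision_rate` — an already-used one, and samples 100 bp
read pairs (insert 300 ± 30 bp) along the fragment to 0.2× per-fragment
depth until the species reaches its target fold-coverage. Sequencing
errors are substitutions only. Every read carries truth labels (genome,
fragment, region class), assigned so that region labels predict classifier
behaviour exactly for error-free reads.

The mock preset mirrors a standard ten-member community: eight members at
12% relative abundance and two at 2%, scaled onto 50 kb miniature genomes
at 250× total coverage so the full pipeline runs in minutes. With those
genome sizes the 2% members sit below the 10× gate, exercising the skip
path.

What the simulator does **not** model: indel sequencing errors, quality
values and GC bias, strain mixtures within a species, rearrangements
(insertions are novel sequence, not translocations), and realistic
fragment-per-barcode counts (a collision adds a single extra fragment).
Passing tests therefore demonstrate the algorithmic behaviour of the
stages, not performance on real stLFR libraries.

## Toy assembler

The built-in assembler builds a canonical de Bruijn graph (k = 31) from
k-mers with count ≥ 2 and emits maximal non-branching paths of ≥ 2k bp,
walking from lexicographically smallest start k-mers for determinism.
Below-threshold k-mers are rescued when (a) no solid k-mer shares their
(k−1)-prefix or (k−1)-suffix — a sequencing-error k-mer always competes
with the solid true k-mer, a coverage-dip k-mer does not — and (b) they
are reachable from the solid graph, so isolated weak islands stay
excluded. This keeps low-coverage assemblies (around the 10× gate) from
fragmenting at Poisson coverage dips while still dropping error k-mers.
On error-free reads every contig is an exact substring of the source
genome (up to reverse complement), which the evaluation oracles exploit.

## Alignment, ANI/AF and variants

The built-in aligner seeds with exact 19-mers (reference occurrences
capped at 20), chains anchors greedily with ≤ 20 kb gaps, and breaks a
chain when the anchor diagonal jumps ≥ 500 bp — so a large novel insertion
separates two local alignments instead of poisoning one global one. Each
chain span (±100 bp flank) is aligned globally with edlib. Two
post-passes make the CIGARs behave like an affine-gap aligner's: regions
between ≥ 15 bp match anchors that contain more than one indel run are
re-aligned with affine gap scores (match 1, mismatch −4, open −8, extend
−0.2), because unit-cost edit distance shreds long indels into scattered
gaps of equal cost; and alignment ends are trimmed back to the outermost
≥ 15 bp match run. Alignments are finally split at indel runs ≥ 1 kb.

Decontamination and evaluation semantics:

* ANI of one alignment = 100 × matches / block length, where the block
  counts match, mismatch, inserted **and** deleted columns (the
  gap-inclusive denominator; stated explicitly because "identity" is
  otherwise ambiguous).
* AF merges the **contig-coordinate** intervals of alignments with ANI
  strictly > 90%; contigs are kept at AF strictly > 50% (AF exactly 0.5
  drops). Interval merging is a sort-and-sweep; a per-base bitmap oracle
  checks it in the tests.
* Genome fraction merges **reference-coordinate** intervals at identity
  strictly > 95%. N50 is computed against the assembly size, NG50 against
  the reference size (0 when the assembly is under half the reference);
  NGA50 would require misassembly breaking and is out of scope.
* Valid fragments: per (barcode, reference), read-pair placements sorted
  by start split into clusters at gaps > 50 kb (the gap threshold is a
  package choice, exposed as a flag); a cluster is valid iff it has
  strictly more than 5 pairs and spans strictly more than 10 kb.
* Variants walk extended CIGARs of alignments covering ≥ 10 kb of
  reference. Mismatches are SNVs; single-base indels are ignored
  entirely; 2–49 bp indels are small, ≥ 50 bp large. Indel records are
  VCF-style anchored on the preceding reference base; positions are
  0-based internally and 1-based in VCF output. Cross-sample sharing keys
  on (species, reference, position, ref, alt). SNV density is reported per
  100 kb of aligned reference — the unit is a package convention.
* Truth-based quality: contig origin is assigned by canonical k-mer
  voting against the sample genomes; completeness is the fraction of the
  target genome covered (ANI > 90%) by its own contigs, contamination the
  fraction of contig bases with a foreign origin. The standard MAG tiers
  apply: high = completeness > 90 ∧ contamination < 5; medium =
  completeness > 50 ∧ contamination < 10 (excluding high); else low. This
  replaces marker-gene completeness estimation, which is meaningless for
  synthetic random genomes.

## Orchestration

`run_pipeline` executes classify → refine → assemble → decontaminate →
evaluate per species, in ascending taxid order, sequentially: per-species
work at these problem sizes is seconds, and sequential execution makes the
manifest trivially deterministic (the `parallel_species` knob is accepted
for interface compatibility). A failure in one species is recorded in the
manifest and does not block the others.

## Problem sizes

Tests use 15–50 kb genomes at 12–50× with 3–10 species; the end-to-end
acceptance run uses five 50 kb species (50/30/20/12/5×, one below the
gate) and the acceptance script a ten-species mock at 250× total. These
sizes keep the whole suite in minutes on one CPU while exercising every
stage, including the cap, the gate, collisions and all three read regimes.

## Known limitations

* The toy assembler has no paired-end awareness, no scaffolding and no
  bubble popping; heterozygosity or strain mixtures would fragment it.
* The toy aligner assumes mostly-collinear, high-identity alignments; it
  is not a general-purpose aligner and alignments below ~75% identity are
  simply not found (which decontamination treats as AF = 0).
* Classification at k = 31 with error-free references is far cleaner than
  real Kraken2 against real databases; real communities will show lower
  species-level assignment and abundance estimates.
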
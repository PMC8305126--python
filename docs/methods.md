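# Methods

## Scope and model

`amplimon` models a short-amplicon multiplex-PCR ctDNA assay with dual
12-nt UMIs and a fixed universal tag on both ends of every molecule.  The
pipeline's unit of evidence is the *unique tagged molecule*: only read
pairs that assemble perfectly, show the expected tag and primer structure,
and come from a UMI pair observed exactly once contribute to the pileup.
Sensitivity therefore comes from depth of unique molecules, and
specificity from the fact that a sequencing or late-PCR error must survive
a perfect-overlap assembly, a quality gate and the alternate-count /
frequency thresholds before it can be reported.

Amplicon coordinates are anchored to the genome by the amplicon's start
position: amplicon position `k` (1-based) maps to `amplicon_start + k - 1`.
For every panel region that fits under the 285-bp product cap the fixture
amplicon coincides with the printed region, so a call at amplicon offset
`k` on a target starting at `S` has VCF position `S + k - 1`.  The one
region longer than the cap (the TP53 exon 5-8 block) is covered by a
200-bp amplicon centred on the region midpoint, so the mid-base coverage
site is always inside the product; the invariant "the product spans its
region" is correspondingly weakened to "the product contains the region's
midpoint" for such regions.

## Filtering parameters

| parameter | default | meaning |
|---|---|---|
| `max_low_bases` | 30 bases | sub-Q28 budget per read pair (10% of 300 bp) |
| `q_threshold` | Q28 | quality boundary for the level-1 gate and the pileup |
| `min_overlap` | 15 nt | minimum zero-mismatch R1/R2 overlap |
| `tag_max_deviation` | 2 bases | per-end tag mismatch budget |
| `primer_max_hamming` | 3 bases | per-primer mismatch budget |
| `umi_length` | 12 nt | UMI length on each end |

Decisions that the parameters alone do not pin down:

- **The 30-base budget is counted jointly over both mates** (10% of the
  overall maximum pair length).  A per-mate reading is also defensible;
  the joint reading is the stricter and simpler of the two.
- **All end comparisons are ungapped mismatch counts** (Hamming, no
  indels).  Local alignment would tolerate indels that the no-indel
  primer-design rule and the downstream fixed-length pileup cannot
  represent; end-anchored comparison also makes every step reproducible
  against a brute-force oracle.
- **Merging requires a *unique* zero-mismatch overlap of >= 15 nt.**
  Without a minimum, 1-2 nt chance overlaps would merge unrelated mates;
  without uniqueness, repetitive constructs could assemble ambiguously.
  Overlap base qualities take the per-position maximum of the two mates,
  since both mates must agree for the pair to merge at all.
- **The tag check runs between assembly and primer trimming**, i.e. on
  the assembled read, where both tag copies are visible at once.
- **UMI clustering is exact-match and discards clusters > 1 read** rather
  than collapsing them to a consensus.  This trades depth for simplicity
  and for a hard guarantee that no PCR duplicate is counted twice.
  Reads failing UMI extraction (too short to contain two UMIs plus an
  insert) are counted with the level-3 structural removals.

## Calling parameters

| parameter | default | meaning |
|---|---|---|
| `min_alt_fraction` | 0.0015 | reporting floor (0.15%) |
| `min_alt_count` | 4 reads | minimum alternate support |
| `min_base_quality` | Q28 | pileup inclusion threshold |
| `standalone_fraction` | 0.005 | tier boundary (0.5%) |
| `min_target_reads` | 1000 reads | per-target QC floor |

All thresholds are inclusive (`>=`), matching the `min-*` parameter
semantics of pileup-style callers; the boundary behaviour is pinned by
tests.  Calls in `[0.15%, 0.5%)` are positive only when the same
(target, position, ref, alt) key appears in the supplied matched-tumor
set; any supplied tumor variant counts, with no pathogenicity filter.
Unconfirmed calls in that band are retained with tier
`suppressed_needs_confirmation` and a VCF FILTER tag, but excluded from
the positive list.  The caller is substitution-only: the upstream
no-indel model rejects length-changed reads before the pileup, and the
panel's hotspots are substitution hotspots.

## Simulator

The generator emulates, per sample: template sampling (wild-type copies
per target, Poisson-realized mutant copies — fractional means such as 1.6
copies are meaningful as dilution expectations), UMI tagging, PCR
duplication with per-copy substitution errors, and 2x150 sequencing with
a per-cycle quality profile and quality-coupled substitution errors.
Identical seeds give byte-identical FASTQ.

Key modelling choices:

- **UMI tagging yield** (`tags_per_template`, default 8, Poisson).
  Tagged primers label products over the first PCR cycles on both
  strands, so one input template yields several distinct UMI-pair
  molecules — of the order of 2^3 for tagging through the first three
  cycles.  This layer is essential to the assay's arithmetic: with a
  strict discard-duplicates rule, deduplicated alternate reads can never
  exceed the number of tagged mutant molecules, so a handful of mutant
  templates is only detectable because each spawns several tagged
  products.
- **PCR duplication factor** per tagged molecule is geometric with mean
  10 (configurable); it exists to exercise the deduplication level, and
  its interplay with read depth sets the singleton-cluster fraction.
- **PCR substitution rate** defaults to 1e-5 per base per copy, a
  high-fidelity-polymerase figure; PCR errors carry normal qualities and
  are the main residual false-positive channel.
- **Sequencing errors are coupled to quality**: a base errs with
  probability proportional to `10^(-Q/10)`, scaled so the mean equals
  `substitution_rate_seq` (default 0.1%).  This is the Phred semantics;
  it concentrates errors in low-quality bases, which the Q28 pileup gate
  and the perfect-overlap assembly then remove.  The quality profile is
  97% of bases at Q30-41 and 3% at Q2-27; additionally 0.5% of reads are
  "degraded" (25% low-quality bases), which is what gives the level-1
  gate a small but nonzero removal fraction.
- **Reads start at the universal tag**: indexing chemistry, adapters and
  spacer diversity bases are upstream of the modelled construct, as after
  demultiplexing.  R2 is stored reverse-complemented per paired-end
  convention.  For constructs shorter than 150 bp both mates read the
  full construct.
- **Matched tumor samples** default to 5,000 input templates (tissue DNA
  is not plasma-limited) with per-template Bernoulli allele assignment,
  so template-sampling noise stays well below read-sampling noise when
  re-measuring a 30% variant.

Not emulated: indels, cfDNA fragment-length physics, GC and primer
efficiency bias, UMI sequencing errors creating phantom molecules, CHIP
variants, and inter-run batch effects.  Passing tests on this generator
therefore demonstrates the pipeline's arithmetic and thresholds, not
performance on real plasma.

## Benchmark design

The dilution benchmark simulates the spike-in series on the spiked
target's *single-amplicon sub-panel* with the full 10,000-read budget,
because a spike-in experiment characterizes the assay at the known SNP
locus and reads on other amplicons carry no information about it.
"Detection" means the spiked variant is reported with a positive tier,
with the variant supplied as tumor-confirmed (its identity is known a
priori).  At 640 wild-type copies, ~8 tags per template and ~10,000
reads, a level's expected deduplicated depth is ~1,300 unique molecules,
so the 1% tier (6.4 copies) yields around a dozen alternate molecules —
comfortably above the 4-read floor, while the same arithmetic spread
over 21 amplicons would leave ~2 alternate molecules and no valid call.
Healthy-donor specificity samples run on the full 21-target panel with an
empty tumor set.  Problem sizes used by the test suite and the acceptance
script (12 healthy samples, 3 replicates per level, 10,000 read pairs per
sample, 20-seed recovery checks at 1,500 reads) are the package's chosen
desk-scale operating points.

The VAF-recovery property asserts that a 30% tumor variant is re-measured
inside the exact binomial 99% interval at the deduplicated depth in at
least 18 of 20 seeded runs: a perfectly calibrated 99% interval itself
misses about 0.2 of 20 runs, so demanding 20/20 would reject a correct
implementation roughly one time in five.

## Worked-example snippet

The README's worked example prints its numbers with:

```python
st = result.filter_stats
print(f"input pairs      {st.input_pairs}")
print(f"level 1 removed  {st.removed_level1}")
print(f"level 2 removed  {st.removed_level2}")
print(f"tag check        {st.removed_tagcheck}")
print(f"level 3 removed  {st.removed_level3}")
print(f"level 4 removed  {st.removed_level4_reads}")
print(f"dedup survivors  {st.survivors}")
print(f"theoretical VAF  {scenario.theoretical_vaf:.4f}")
for call in result.positive_calls:
    print(f"call: {call.chrom}:{call.genome_pos} {call.ref}>{call.alt} "
          f"AF={call.frequency:.4f} ({call.alt_count}/{call.depth}) tier={call.tier}")
```

## Degenerate inputs and tie-breaks

- Empty panels export empty BED files; an empty sample fails QC listing
  every target.
- The hairpin screen requires `len(primer) >= 2*min_stem + 3` (shorter
  primers cannot contain a reportable hairpin) and raises otherwise.
- Fixture primers are random 20-mers accepted by rejection sampling
  against the package's own dimer (3' run <= 5) and hairpin (stem < 6)
  screens, like a designed panel would be.
- Caller output order is (target, position, alt); deduplication output
  order is sorted by (target, UMI5, UMI3); reports are byte-deterministic
  for fixed inputs.
- `variant x timepoint` trajectories distinguish "absent in a QC-passing
  sample" (0.0) from "sample failed QC" (missing).

## Known limitations

- Specificity against real error modes (oxidative damage, FFPE
  deamination, CHIP) is outside the simulator's reach; the 100%
  healthy-cohort specificity computed here reflects the modelled error
  channels only.
- The discard-duplicates rule wastes the majority of reads at high
  duplication; a consensus-collapsing mode is deliberately not offered.
- Genome-wide alignment is replaced by primer-based unique assignment,
  which is equivalent at amplicon scale but blind to off-panel
  mispriming products that happen to match a primer pair within 3
  mismatches.
- No quantitative progression rule is implemented; new-variant flagging
  is structural (set difference against tumor and baseline), not
  clinical interpretation.
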
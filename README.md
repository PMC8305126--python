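# amplimon

Amplicon-based circulating tumor DNA (ctDNA) monitoring for deep-sequenced
multiplex PCR panels with dual unique molecular identifiers (UMIs).  The
package is aimed at people building or validating liquid-biopsy assays: it
bundles a breast-cancer hotspot panel model (21 regions across 12 genes such
as *PIK3CA*, *TP53*, *ESR1*, *ERBB2/HER2*, *AKT1*), a seeded read simulator
with known truth, a strict four-level read-filtering stack, a transparent
low-frequency pileup caller with matched-tumor tiering, and longitudinal
tracking of variant allele frequencies (VAF) across serial plasma samples.

## The method

Each library molecule has the layout

```
tag + UMI(12 nt) + fwd primer + insert + rc(rev primer) + rc(UMI(12 nt)) + rc(tag)
```

with amplicons kept under 285 bp so 2x150 paired-end reads always overlap.
Reads pass four filters, in order:

1. **Quality gate** — at most 30 bases below Q28 per read pair (10% of the
   300-bp pair).
2. **Perfect assembly** — R1/R2 must share a unique zero-mismatch overlap;
   then a **tag check** requires the universal tag at both ends within 2
   mismatches.
3. **Primer trimming** — after UMI extraction, the read must match exactly
   one panel primer pair within 3 mismatches per primer (end-anchored,
   no indels); this uniquely assigns the read to a target.
4. **UMI deduplication** — reads are clustered by exact
   (target, UMI5, UMI3) key and every cluster with more than one read is
   discarded, eliminating all possible PCR duplicates.

Variants are called from quality-gated pileups of the deduplicated reads: a
substitution with alternate count `AO >= 4` and frequency
`AF = AO/DP >= 0.15%` is reported — *standalone* when `AF >= 0.5%`,
*tumor-confirmed* when `0.15% <= AF < 0.5%` and the same variant was seen in
the patient's tumor tissue, otherwise retained but *suppressed*.  A sample
passes QC when every target keeps >= 1000 filtered reads.  Longitudinal
monitoring tabulates per-variant AF trajectories over serial samples and
flags variants absent from both tumor and baseline plasma that appear later.

## Worked example

Spike 16 mutant template copies into 640 wild-type copies (theoretical VAF
2.44%) on the *PIK3CA* H1047 amplicon, sequence 10,000 read pairs, and run
the full pipeline:

```python
from amplimon.simulate import (default_panel, default_spike_variant,
                               DilutionScenario, simulate_sample)
from amplimon.varcall import process_sample

panel = default_panel()
variant = default_spike_variant(panel)        # PIK3CA hotspot amplicon SNV
spike = panel.subset([variant[0]])

scenario = DilutionScenario(variant_id=variant, variant_copies=16,
                            wt_copies=640, reads_per_sample=10_000)
sample = simulate_sample(spike, scenario, seed=11, sample_id="spike16")
result = process_sample(sample, spike, tumor_variants={variant},
                        sample_id="spike16")
```

prints (via the snippet in `docs/methods.md`):

```
input pairs      10000
level 1 removed  114
level 2 removed  2290
tag check        0
level 3 removed  0
level 4 removed  6244
dedup survivors  1352
theoretical VAF  0.0244
call: 3:179234244 T>A AF=0.0185 (25/1350) tier=standalone
```

The quality gate removes ~1% of pairs, the perfect-overlap assembly rejects
pairs with any sequencing error in the overlap, and deduplication keeps only
single-read UMI clusters (1,352 unique molecules here).  The spiked variant
is recovered at 1.85% measured VAF — within sampling noise of the 2.44%
expectation — and reported standalone since it exceeds 0.5%.

The same stages are exposed on the command line:

```bash
amplimon panel bed                 # panel as 0-based BED
amplimon panel validate            # primer uniqueness / dimer / hairpin checks
amplimon simulate dilution --out sim --seed 1
amplimon call --r1 R1.fastq.gz --r2 R2.fastq.gz --out calls
amplimon monitor benchmark --out bench --seed 1
```

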
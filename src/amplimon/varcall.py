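"""Low-frequency pileup variant calling with matched-tumor tiering.

Deduplicated, primer-trimmed reads are stacked against their amplicon
reference (unique target assignment has already been enforced upstream by
primer matching).  Bases below Q28 are excluded from the counts.  A
substitution is reported when it has at least ``min_alt_count`` (default
4) supporting reads and a frequency of at least ``min_alt_fraction``
(default 0.15%).  Calls at [0.15%, 0.5%) are accepted only when the same
variant is present in the patient's matched tumor tissue
(``tumor_confirmed``); calls at >= 0.5% stand alone.  Unconfirmed
low-frequency observations are retained with tier
``suppressed_needs_confirmation`` but excluded from the positive list.

Threshold semantics are inclusive (>=) throughout, matching the min-*
parameter convention of pileup-style callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import PanelDefinition
from .readfilter import FilterConfig, FilterStats, MergedRead, run_filter_stack
from .util import BASES, chrom_sort_key, seq_to_ints

TIER_STANDALONE = "standalone"
TIER_TUMOR_CONFIRMED = "tumor_confirmed"
TIER_SUPPRESSED = "suppressed_needs_confirmation"
POSITIVE_TIERS = (TIER_STANDALONE, TIER_TUMOR_CONFIRMED)

VariantKey = tuple[str, int, str, str]  # (target_id, amplicon pos 1-based, ref, alt)


@dataclass
class CallerConfig:
    min_alt_fraction: float = 0.0015
    min_alt_count: int = 4
    min_base_quality: int = 28
    standalone_fraction: float = 0.005
    min_target_reads: int = 1000

    def __post_init__(self):
        if not (0 < self.min_alt_fraction <= self.standalone_fraction < 1):
            raise ValueError(
                "require 0 < min_alt_fraction <= standalone_fraction < 1"
            )
        if self.min_alt_count < 1:
            raise ValueError("min_alt_count must be >= 1")


@dataclass
class Pileup:
    """Per-position base counts over one amplicon insert.

    ``counts`` has shape (insert_length, 4) in A/C/G/T order and includes
    only bases at or above the caller's quality threshold.  Positions are
    reported 1-based within the amplicon: insert index i corresponds to
    amplicon position ``core_offset + i + 1`` and genomic position
    ``genome_start + core_offset + i`` when a genomic anchor is known.
    """

    target_id: str
    ref_insert: str
    counts: np.ndarray
    core_offset: int = 0
    chrom: str = ""
    genome_start: int | None = None  # 1-based genomic pos of amplicon base 1
    reads_used: int = 0
    reads_skipped: int = 0

    def depth(self, i: int) -> int:
        return int(self.counts[i].sum())

    @classmethod
    def from_counts(
        cls, target_id: str, ref_insert: str, counts, **kwargs
    ) -> "Pileup":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(ref_insert), 4):
            raise ValueError("counts must have shape (len(ref_insert), 4)")
        return cls(target_id=target_id, ref_insert=ref_insert, counts=counts, **kwargs)


@dataclass
class VariantCall:
    target_id: str
    position: int  # 1-based within the amplicon
    chrom: str
    genome_pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    frequency: float
    tier: str
    sample_qc_pass: bool = True

    @property
    def key(self) -> VariantKey:
        return (self.target_id, self.position, self.ref, self.alt)

    @property
    def is_positive(self) -> bool:
        return self.tier in POSITIVE_TIERS


@dataclass
class SampleResult:
    sample_id: str
    coverage: dict[str, int]
    read_counts: dict[str, int]
    filter_stats: FilterStats | None
    variants: list[VariantCall]
    qc_pass: bool
    qc_failures: dict[str, int] = field(default_factory=dict)

    @property
    def positive_calls(self) -> list[VariantCall]:
        return [v for v in self.variants if v.is_positive]


# ---------------------------------------------------------------------------
# Pileup construction
# ---------------------------------------------------------------------------

def build_pileups(
    reads: list[MergedRead],
    panel: PanelDefinition,
    config: CallerConfig | None = None,
) -> dict[str, Pileup]:
    """Stack deduplicated reads against their amplicon references.

    Bases below ``min_base_quality`` are excluded from the counts.  Reads
    whose length differs from the reference insert are skipped and counted
    (the model upstream admits no indels, so a length mismatch means a
    corrupt read).
    """
    cfg = config or CallerConfig()
    pileups: dict[str, Pileup] = {}
    for p in panel.primers:
        tid = p.target_id
        amp = panel.reference[tid]
        lf, lr = len(p.fwd), len(p.rev)
        insert = amp[lf : len(amp) - lr]
        pileups[tid] = Pileup(
            target_id=tid,
            ref_insert=insert,
            counts=np.zeros((len(insert), 4), dtype=np.int64),
            core_offset=lf,
            chrom=panel.target(tid).chrom,
            genome_start=p.amplicon_start or panel.target(tid).start,
        )
    for r in reads:
        pu = pileups.get(r.target_id)
        if pu is None:
            continue
        if len(r.seq) != len(pu.ref_insert):
            pu.reads_skipped += 1
            continue
        ints = seq_to_ints(r.seq)
        ok = np.asarray(r.qual) >= cfg.min_base_quality
        np.add.at(pu.counts, (np.nonzero(ok)[0], ints[ok]), 1)
        pu.reads_used += 1
    return pileups


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_variants(
    pileups: dict[str, Pileup] | list[Pileup],
    tumor_variants: frozenset[VariantKey] | set[VariantKey] = frozenset(),
    config: CallerConfig | None = None,
) -> list[VariantCall]:
    """Call substitutions from pileups with tumor-confirmation tiering.

    Output is deterministic, ordered by (target, position, alt).  All
    qualifying non-reference observations are returned, including
    suppressed ones; filter on ``is_positive`` for the reportable list.
    """
    cfg = config or CallerConfig()
    if isinstance(pileups, dict):
        pile_list = [pileups[k] for k in sorted(pileups)]
    else:
        pile_list = sorted(pileups, key=lambda p: p.target_id)
    calls: list[VariantCall] = []
    for pu in pile_list:
        ref_ints = seq_to_ints(pu.ref_insert)
        depths = pu.counts.sum(axis=1)
        nonref = pu.counts.copy()
        nonref[np.arange(len(ref_ints)), ref_ints] = 0
        cand_pos, cand_alt = np.nonzero(nonref >= cfg.min_alt_count)
        for i, a in zip(cand_pos, cand_alt):
            depth = int(depths[i])
            alt_count = int(pu.counts[i, a])
            freq = alt_count / depth
            if freq < cfg.min_alt_fraction:
                continue
            position = pu.core_offset + int(i) + 1
            key = (pu.target_id, position, pu.ref_insert[int(i)], BASES[int(a)])
            if freq >= cfg.standalone_fraction:
                tier = TIER_STANDALONE
            elif key in tumor_variants:
                tier = TIER_TUMOR_CONFIRMED
            else:
                tier = TIER_SUPPRESSED
            genome_pos = (
                pu.genome_start + position - 1
                if pu.genome_start is not None
                else position
            )
            calls.append(
                VariantCall(
                    target_id=pu.target_id,
                    position=position,
                    chrom=pu.chrom,
                    genome_pos=genome_pos,
                    ref=pu.ref_insert[int(i)],
                    alt=BASES[int(a)],
                    alt_count=alt_count,
                    depth=depth,
                    frequency=freq,
                    tier=tier,
                )
            )
    calls.sort(key=lambda c: (c.target_id, c.position, c.alt))
    return calls


# ---------------------------------------------------------------------------
# Coverage and QC
# ---------------------------------------------------------------------------

def compute_coverage(
    reads: list[MergedRead], panel: PanelDefinition
) -> dict[str, int]:
    """Mid-base coverage: reads whose trimmed insert spans the 1-bp region
    midpoint of their target (the non-overlapping middle base)."""
    coverage = {p.target_id: 0 for p in panel.primers}
    spans: dict[str, tuple[int, int]] = {}
    for p in panel.primers:
        t = panel.target(p.target_id)
        astart0 = (p.amplicon_start or t.start) - 1
        insert_start0 = astart0 + len(p.fwd)
        spans[p.target_id] = (insert_start0, t.midpoint0)
    for r in reads:
        if r.target_id not in spans:
            continue
        insert_start0, mid0 = spans[r.target_id]
        if insert_start0 <= mid0 < insert_start0 + len(r.seq):
            coverage[r.target_id] += 1
    return coverage


def qc_sample(
    read_counts: dict[str, int],
    panel: PanelDefinition,
    config: CallerConfig | None = None,
) -> tuple[bool, dict[str, int]]:
    """Pass iff every panel target has at least ``min_target_reads``
    filtered reads; returns the failing targets with their counts."""
    cfg = config or CallerConfig()
    failures = {}
    for t in panel.targets:
        n = read_counts.get(t.target_id, 0)
        if n < cfg.min_target_reads:
            failures[t.target_id] = n
    return (len(failures) == 0, failures)


# ---------------------------------------------------------------------------
# End-to-end per-sample pipeline
# ---------------------------------------------------------------------------

def process_sample(
    source,
    panel: PanelDefinition,
    filter_config: FilterConfig | None = None,
    caller_config: CallerConfig | None = None,
    tumor_variants: frozenset[VariantKey] | set[VariantKey] = frozenset(),
    sample_id: str = "sample",
) -> SampleResult:
    """Filter stack -> pileups -> calls -> coverage -> QC for one sample."""
    cfg = caller_config or CallerConfig()
    reads, stats = run_filter_stack(source, panel, filter_config)
    pileups = build_pileups(reads, panel, cfg)
    calls = call_variants(pileups, tumor_variants, cfg)
    coverage = compute_coverage(reads, panel)
    read_counts = {tid: pu.reads_used for tid, pu in pileups.items()}
    qc_pass, failures = qc_sample(read_counts, panel, cfg)
    for c in calls:
        c.sample_qc_pass = qc_pass
    return SampleResult(
        sample_id=sample_id,
        coverage=coverage,
        read_counts=read_counts,
        filter_stats=stats,
        variants=calls,
        qc_pass=qc_pass,
        qc_failures=failures,
    )


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_FILTER_SUPPRESSED = "LowFreqUnconfirmed"


def write_vcf(
    calls: list[VariantCall],
    panel: PanelDefinition | None = None,
    sample_id: str = "sample",
) -> str:
    """Render calls as VCF 4.2 text with genomic coordinates.

    Suppressed calls are emitted with FILTER=LowFreqUnconfirmed; positive
    tiers are PASS.  INFO carries depth, alternate count, frequency, tier
    and the source amplicon.
    """
    chroms: list[str] = []
    if panel is not None:
        chroms = sorted({t.chrom for t in panel.targets}, key=chrom_sort_key)
    else:
        chroms = sorted({c.chrom for c in calls if c.chrom}, key=chrom_sort_key)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=amplimon sample={sample_id}",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Deduplicated read depth">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate observation count">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">',
        '##INFO=<ID=TIER,Number=1,Type=String,Description="Reporting tier">',
        '##INFO=<ID=TARGET,Number=1,Type=String,Description="Amplicon target id">',
        f'##FILTER=<ID={_VCF_FILTER_SUPPRESSED},'
        'Description="Frequency in the confirmation band without matched-tumor support">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = sorted(
        calls, key=lambda c: (chrom_sort_key(c.chrom), c.genome_pos, c.alt)
    )
    for c in ordered:
        filt = "PASS" if c.is_positive else _VCF_FILTER_SUPPRESSED
        info = (
            f"DP={c.depth};AO={c.alt_count};AF={c.frequency:.6f};"
            f"TIER={c.tier};TARGET={c.target_id}"
        )
        lines.append(
            f"{c.chrom or '.'}\t{c.genome_pos}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}"
        )
    return "\n".join(lines) + "\n"
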
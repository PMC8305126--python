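"""Seeded read simulator for dual-UMI multiplex amplicon libraries.

Generates 2x150 paired-end reads with the full library structure
(universal tag + 12-nt UMI + gene-specific primer on both ends) and a
known truth set, so every downstream stage can be tested without patient
data.  The molecule model is:

1. *Templates.*  Each target receives ``wt_copies`` wild-type template
   molecules; a spiked variant contributes Poisson(variant_copies) mutant
   templates (fractional copy numbers are physical: the expected number of
   template molecules in a dilution aliquot).
2. *UMI tagging.*  Tagged primers label products over the first PCR
   cycles, so one input template yields several distinct UMI-pair-tagged
   molecules; each template produces Poisson(``tags_per_template``,
   default 8) tagged molecules, each with independent 12-nt UMIs on both
   ends.
3. *PCR duplication.*  Each tagged molecule is amplified to a
   geometric(mean ``pcr_duplication_mean``, default 10) number of copies;
   each copy independently acquires substitutions at
   ``substitution_rate_pcr`` per base.
4. *Sequencing.*  ``reads_per_sample`` read pairs are drawn from the copy
   pool.  Per-base qualities follow the configured profile and
   substitution errors are coupled to quality (probability proportional
   to 10^(-Q/10), scaled to the configured mean rate), so most errors
   carry low quality scores, as on a real instrument.

Identical seeds give byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    LibraryStructure,
    PanelDefinition,
    PanelError,
    PrimerPair,
    _three_prime_run,
    check_hairpin,
    load_bundled_panel,
)
from .readfilter import ReadPair, write_fastq_pairs
from .util import BASES, ints_to_seq, random_dna, revcomp, seq_to_ints

DEFAULT_DILUTION_COPIES = (0.0, 1.6, 3.2, 6.4, 16.0, 32.0, 320.0)
DEFAULT_WT_COPIES = 640
DEFAULT_READS_PER_SAMPLE = 10_000
DEFAULT_TAGS_PER_TEMPLATE = 8.0
DEFAULT_PCR_DUPLICATION_MEAN = 10.0
_FIXTURE_PRIMER_SEED = 42
_FIXTURE_REFERENCE_SEED = 43
_READ_LENGTH = 150


class SimulationError(ValueError):
    pass


@dataclass
class ErrorModel:
    """Error and quality profile of library prep plus sequencing.

    ``substitution_rate_seq`` is the mean per-base sequencing substitution
    rate; individual bases err with probability proportional to
    10^(-Q/10) given their drawn quality.  A small fraction of reads is
    "degraded" (burst of low-quality cycles), which is what makes the
    level-1 quality gate remove a visible fraction of pairs.
    """

    substitution_rate_pcr: float = 1e-5
    substitution_rate_seq: float = 1e-3
    low_q_fraction: float = 0.03
    q_low: tuple[int, int] = (2, 27)
    q_high: tuple[int, int] = (30, 41)
    degraded_read_rate: float = 0.005
    degraded_low_q_fraction: float = 0.25
    seed: int | None = None

    def __post_init__(self):
        for name in ("substitution_rate_pcr", "substitution_rate_seq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise SimulationError(f"{name}={v} outside [0, 0.1]")
        for lo, hi in (self.q_low, self.q_high):
            if not (2 <= lo <= hi <= 41):
                raise SimulationError("quality scores must lie in [2, 41]")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(
            substitution_rate_pcr=0.0,
            substitution_rate_seq=0.0,
            low_q_fraction=0.0,
            degraded_read_rate=0.0,
        )

    def mean_phred_error(self) -> float:
        """E[10^(-Q/10)] under the baseline quality profile."""

        def mean_err(lo, hi):
            qs = np.arange(lo, hi + 1)
            return float(np.mean(10.0 ** (-qs / 10.0)))

        return (1.0 - self.low_q_fraction) * mean_err(*self.q_high) + (
            self.low_q_fraction
        ) * mean_err(*self.q_low)

    def error_scale(self) -> float:
        """Scale factor mapping 10^(-Q/10) to per-base error probability."""
        if self.substitution_rate_seq == 0.0:
            return 0.0
        return self.substitution_rate_seq / self.mean_phred_error()


@dataclass
class DilutionScenario:
    """One spike-in condition: variant copies against a wild-type background."""

    variant_id: tuple[str, int, str, str] | None = None
    variant_copies: float = 0.0
    wt_copies: int = DEFAULT_WT_COPIES
    reads_per_sample: int = DEFAULT_READS_PER_SAMPLE
    replicates: int = 3

    def __post_init__(self):
        if self.variant_copies < 0:
            raise SimulationError("variant_copies must be >= 0")
        if self.wt_copies < 1:
            raise SimulationError("wt_copies must be >= 1")

    @property
    def theoretical_vaf(self) -> float:
        if self.variant_copies == 0:
            return 0.0
        return self.variant_copies / (self.variant_copies + self.wt_copies)


@dataclass
class TruthVariant:
    variant_id: tuple[str, int, str, str]
    theoretical_vaf: float
    realized_templates: int
    tagged_molecules: int
    wt_templates: int

    @property
    def realized_template_fraction(self) -> float:
        tot = self.realized_templates + self.wt_templates
        return self.realized_templates / tot if tot else 0.0


@dataclass
class SampleTruth:
    sample_id: str
    variants: list[TruthVariant] = field(default_factory=list)
    wt_templates: dict[str, int] = field(default_factory=dict)


class MoleculePool:
    """Tagged-molecule bookkeeping (arrays; constructs built lazily)."""

    def __init__(self, tag: str):
        self.tag_arr = seq_to_ints(tag)
        self.alleles: list[np.ndarray] = []  # amplicon sequences (ints)
        self.allele_target: list[str] = []
        self.allele_is_variant: list[bool] = []
        self._allele_of_mol: list[np.ndarray] = []
        self.umis: np.ndarray | None = None  # (n, 24) uint8
        self.copies: np.ndarray | None = None

    def add_allele(self, target_id: str, amplicon: np.ndarray, n_molecules: int,
                   is_variant: bool) -> None:
        idx = len(self.alleles)
        self.alleles.append(amplicon)
        self.allele_target.append(target_id)
        self.allele_is_variant.append(is_variant)
        self._allele_of_mol.append(np.full(n_molecules, idx, dtype=np.int32))

    def finalize(self, rng: np.random.Generator, dup_mean: float) -> None:
        self.allele_of_mol = (
            np.concatenate(self._allele_of_mol)
            if self._allele_of_mol
            else np.zeros(0, dtype=np.int32)
        )
        n = self.allele_of_mol.size
        self.umis = rng.integers(0, 4, size=(n, 24), dtype=np.uint8)
        self.copies = rng.geometric(1.0 / dup_mean, size=n).astype(np.int64)

    @property
    def size(self) -> int:
        return self.allele_of_mol.size

    def umi5(self, i: int) -> str:
        return ints_to_seq(self.umis[i, :12])

    def umi3(self, i: int) -> str:
        return ints_to_seq(self.umis[i, 12:])

    def construct(self, i: int) -> np.ndarray:
        """tag + UMI5 + amplicon + rc(UMI3) + rc(tag), as base indices."""
        amp = self.alleles[self.allele_of_mol[i]]
        u5 = self.umis[i, :12]
        u3rc = (3 - self.umis[i, 12:])[::-1]
        tag = self.tag_arr
        return np.concatenate([tag, u5, amp, u3rc, (3 - tag)[::-1]])


@dataclass
class SimulatedSample:
    sample_id: str
    pairs: list[ReadPair]
    truth: SampleTruth
    pool: MoleculePool
    seed: int

    def write(self, r1_path, r2_path) -> None:
        write_fastq_pairs(self.pairs, r1_path, r2_path)


# ---------------------------------------------------------------------------
# Reference / fixture construction
# ---------------------------------------------------------------------------

def make_fixture_primers(
    panel: PanelDefinition,
    seed: int = _FIXTURE_PRIMER_SEED,
    primer_length: int = 20,
    centered_product: int = 200,
) -> list[PrimerPair]:
    """Deterministic synthetic primer pairs for every panel target.

    For regions that fit under the product cap the amplicon coincides with
    the printed region (product_length = region length, amplicon_start =
    region start); longer regions get a ``centered_product``-bp amplicon
    centred on the region midpoint so the mid-base coverage site is always
    inside the product.

    Primer sequences are drawn at random but, like a designed panel, must
    pass the panel's own screens: no 3'-anchored cross-complement run > 5
    against any other fixture primer (or itself) and no hairpin stem >= 6.
    """
    rng = np.random.default_rng(seed)

    accepted: list[str] = []

    def draw_primer() -> str:
        for _ in range(200):
            cand = random_dna(rng, primer_length)
            if check_hairpin(cand, min_stem=6).flagged:
                continue
            pool = accepted + [cand]
            if any(
                _three_prime_run(cand, other) > 5 or _three_prime_run(other, cand) > 5
                for other in pool
            ):
                continue
            accepted.append(cand)
            return cand
        raise PanelError("could not draw a screen-passing fixture primer")

    primers = []
    for t in panel.targets:
        if t.length + 0 < 2 * primer_length + 1:
            raise PanelError(
                f"target {t.target_id} too short ({t.length} bp) for "
                f"{primer_length}-bp primers"
            )
        if t.length < 230:
            product = t.length
            astart = t.start
        else:
            product = centered_product
            astart = t.midpoint0 + 1 - centered_product // 2
        primers.append(
            PrimerPair(
                target_id=t.target_id,
                fwd=draw_primer(),
                rev=draw_primer(),
                product_length=product,
                amplicon_start=astart,
            )
        )
    return primers


def make_reference(panel: PanelDefinition, seed: int) -> dict[str, str]:
    """Seeded random amplicon references with primers embedded at the ends.

    Each record is fwd + random core + revcomp(rev), of exactly
    product_length bases, keyed by target_id; the result is stored on the
    panel and returned.
    """
    if not panel.primers:
        raise PanelError("panel has no primers; cannot build references")
    rng = np.random.default_rng(seed)
    reference = {}
    for p in panel.primers:
        core_len = p.product_length - len(p.fwd) - len(p.rev)
        core = random_dna(rng, core_len)
        reference[p.target_id] = p.fwd + core + revcomp(p.rev)
    panel.reference = reference
    panel.validate()
    return reference


def reference_fasta(panel: PanelDefinition) -> str:
    out = []
    for p in panel.primers:
        out.append(f">{p.target_id}\n{panel.reference[p.target_id]}\n")
    return "".join(out)


def default_panel(
    panel_def: PanelDefinition | None = None,
    library: LibraryStructure | None = None,
) -> PanelDefinition:
    """Bundled panel equipped with deterministic fixture primers/references."""
    p = panel_def if panel_def is not None else load_bundled_panel()
    if library is not None:
        p.library = library
    p.primers = make_fixture_primers(p, _FIXTURE_PRIMER_SEED)
    make_reference(p, _FIXTURE_REFERENCE_SEED)
    return p


def default_spike_variant(
    panel: PanelDefinition, target_id: str | None = None
) -> tuple[str, int, str, str]:
    """A canonical spike-in SNV in the middle of one amplicon's insert."""
    if target_id is None:
        pik3ca = [t.target_id for t in panel.targets if t.gene == "PIK3CA"]
        target_id = pik3ca[-1] if pik3ca else panel.targets[0].target_id
    primer = panel.primer_for(target_id)
    amp = panel.reference[target_id]
    lf, lr = len(primer.fwd), len(primer.rev)
    core_len = len(amp) - lf - lr
    pos = lf + core_len // 2 + 1  # 1-based within amplicon
    ref = amp[pos - 1]
    alt = BASES[(BASES.index(ref) + 1) % 4]
    return (target_id, pos, ref, alt)


def _validate_variant(
    panel: PanelDefinition, variant_id: tuple[str, int, str, str]
) -> np.ndarray:
    """Check a variant lies in its amplicon insert; return the alt amplicon."""
    target_id, pos, ref, alt = variant_id
    try:
        primer = panel.primer_for(target_id)
    except KeyError:
        raise SimulationError(f"variant target {target_id!r} not in panel")
    amp = panel.reference[target_id]
    lf, lr = len(primer.fwd), len(primer.rev)
    if not (lf + 1 <= pos <= len(amp) - lr):
        raise SimulationError(
            f"variant position {pos} outside the insert of {target_id} "
            f"(valid range {lf + 1}..{len(amp) - lr})"
        )
    if amp[pos - 1] != ref:
        raise SimulationError(
            f"reference base at {target_id}:{pos} is {amp[pos - 1]}, not {ref}"
        )
    if alt == ref or alt not in BASES:
        raise SimulationError(f"invalid alternate base {alt!r}")
    alt_amp = seq_to_ints(amp).copy()
    alt_amp[pos - 1] = BASES.index(alt)
    return alt_amp


# ---------------------------------------------------------------------------
# Core read generation
# ---------------------------------------------------------------------------

def _generate_reads(
    pool: MoleculePool,
    n_reads: int,
    error: ErrorModel,
    rng: np.random.Generator,
    sample_id: str,
) -> list[ReadPair]:
    if n_reads <= 0:
        raise SimulationError("reads_per_sample must be positive")
    if pool.size == 0:
        raise SimulationError("no molecules to sequence")
    copies = pool.copies
    p = copies / copies.sum()
    choice = rng.choice(pool.size, size=n_reads, p=p)
    copy_idx = np.floor(rng.random(n_reads) * copies[choice]).astype(np.int64)

    # Per-base qualities for both mates, drawn up front (R, 2, 150).
    degraded = rng.random((n_reads, 2)) < error.degraded_read_rate
    low_frac = np.where(
        degraded, error.degraded_low_q_fraction, error.low_q_fraction
    )
    shape = (n_reads, 2, _READ_LENGTH)
    low_mask = rng.random(shape) < low_frac[:, :, None]
    q_lo = rng.integers(error.q_low[0], error.q_low[1] + 1, size=shape)
    q_hi = rng.integers(error.q_high[0], error.q_high[1] + 1, size=shape)
    quals = np.where(low_mask, q_lo, q_hi).astype(np.int16)
    scale = error.error_scale()
    if scale > 0:
        p_err = np.minimum(scale * 10.0 ** (-quals / 10.0), 0.75)
        err_mask = rng.random(shape) < p_err
    else:
        err_mask = np.zeros(shape, dtype=bool)
    err_shift = rng.integers(1, 4, size=shape, dtype=np.uint8)

    pcr_rate = error.substitution_rate_pcr
    construct_cache: dict[int, np.ndarray] = {}
    pcr_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray] | None] = {}
    pairs: list[ReadPair] = []
    for i in range(n_reads):
        mol = int(choice[i])
        base = construct_cache.get(mol)
        if base is None:
            base = pool.construct(mol)
            construct_cache[mol] = base
        L = base.size
        seq = base
        if pcr_rate > 0:
            key = (mol, int(copy_idx[i]))
            if key not in pcr_cache:
                k = rng.poisson(L * pcr_rate)
                if k:
                    pcr_cache[key] = (
                        rng.integers(0, L, size=k),
                        rng.integers(1, 4, size=k, dtype=np.uint8),
                    )
                else:
                    pcr_cache[key] = None
            errs = pcr_cache[key]
            if errs is not None:
                seq = base.copy()
                pos_arr, shift_arr = errs
                seq[pos_arr] = (seq[pos_arr] + shift_arr) % 4
        rl = min(_READ_LENGTH, L)
        r1 = seq[:rl].copy()
        r2 = (3 - seq[::-1])[:rl].copy()
        e1 = err_mask[i, 0, :rl]
        e2 = err_mask[i, 1, :rl]
        if e1.any():
            r1[e1] = (r1[e1] + err_shift[i, 0, :rl][e1]) % 4
        if e2.any():
            r2[e2] = (r2[e2] + err_shift[i, 1, :rl][e2]) % 4
        pairs.append(
            ReadPair(
                id=f"{sample_id}:{i}:m{mol}",
                r1_seq=ints_to_seq(r1),
                r2_seq=ints_to_seq(r2),
                r1_qual=quals[i, 0, :rl].copy(),
                r2_qual=quals[i, 1, :rl].copy(),
            )
        )
    return pairs


def _simulate_from_templates(
    panel: PanelDefinition,
    template_spec: dict[str, list[tuple[np.ndarray | None, int, object]]],
    n_reads: int,
    error: ErrorModel,
    rng: np.random.Generator,
    sample_id: str,
    tags_per_template: float,
    pcr_duplication_mean: float,
) -> tuple[list[ReadPair], MoleculePool, dict]:
    """template_spec: target_id -> [(alt_amplicon|None, n_templates, label)]."""
    pool = MoleculePool(panel.library.universal_tag)
    tagged_counts: dict[tuple[str, object], int] = {}
    for t in panel.targets:
        tid = t.target_id
        ref_amp = seq_to_ints(panel.reference[tid])
        for alt_amp, n_templates, label in template_spec.get(tid, []):
            n_tagged = int(rng.poisson(n_templates * tags_per_template))
            tagged_counts[(tid, label)] = n_tagged
            pool.add_allele(
                tid,
                ref_amp if alt_amp is None else alt_amp,
                n_tagged,
                is_variant=alt_amp is not None,
            )
    pool.finalize(rng, pcr_duplication_mean)
    pairs = _generate_reads(pool, n_reads, error, rng, sample_id)
    return pairs, pool, tagged_counts


def simulate_sample(
    panel: PanelDefinition,
    scenario: DilutionScenario,
    error: ErrorModel | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    tags_per_template: float = DEFAULT_TAGS_PER_TEMPLATE,
    pcr_duplication_mean: float = DEFAULT_PCR_DUPLICATION_MEAN,
) -> SimulatedSample:
    """Simulate one plasma sample under a dilution scenario.

    The realized mutant template count is Poisson(variant_copies); every
    target carries ``wt_copies`` wild-type templates.  Returns in-memory
    read pairs plus the truth set; use ``.write()`` for gzipped FASTQ.
    """
    error = error if error is not None else ErrorModel()
    if scenario.reads_per_sample <= 0:
        raise SimulationError("reads_per_sample must be positive")
    rng = np.random.default_rng(seed if seed is not None else error.seed)

    alt_amp = None
    variant_target = None
    if scenario.variant_id is not None:
        alt_amp = _validate_variant(panel, scenario.variant_id)
        variant_target = scenario.variant_id[0]

    truth = SampleTruth(sample_id=sample_id)
    spec: dict[str, list] = {}
    realized_mut = 0
    for t in panel.targets:
        tid = t.target_id
        entries = [(None, scenario.wt_copies, "wt")]
        if tid == variant_target:
            realized_mut = int(rng.poisson(scenario.variant_copies))
            entries.append((alt_amp, realized_mut, "variant"))
        spec[tid] = entries
        truth.wt_templates[tid] = scenario.wt_copies

    pairs, pool, tagged = _simulate_from_templates(
        panel, spec, scenario.reads_per_sample, error, rng, sample_id,
        tags_per_template, pcr_duplication_mean,
    )
    if scenario.variant_id is not None:
        truth.variants.append(
            TruthVariant(
                variant_id=scenario.variant_id,
                theoretical_vaf=scenario.theoretical_vaf,
                realized_templates=realized_mut,
                tagged_molecules=tagged.get((variant_target, "variant"), 0),
                wt_templates=scenario.wt_copies,
            )
        )
    return SimulatedSample(sample_id, pairs, truth, pool, seed)


def draw_template_counts(
    scenario: DilutionScenario, rng: np.random.Generator
) -> int:
    """Realized mutant template count for one aliquot: Poisson(copies)."""
    return int(rng.poisson(scenario.variant_copies))


# ---------------------------------------------------------------------------
# Sample-set builders
# ---------------------------------------------------------------------------

def _child_seed(master_seed: int, *components: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), *[int(c) for c in components]])


def make_dilution_series(
    panel: PanelDefinition,
    copies: tuple[float, ...] = DEFAULT_DILUTION_COPIES,
    wt_copies: int = DEFAULT_WT_COPIES,
    replicates: int = 3,
    reads_per_sample: int = DEFAULT_READS_PER_SAMPLE,
    error: ErrorModel | None = None,
    seed: int = 0,
    variant: tuple[str, int, str, str] | None = None,
    outdir=None,
) -> tuple[list[SimulatedSample], pd.DataFrame]:
    """One sample per (copy level x replicate), deterministically seeded.

    Returns the samples and a manifest linking sample ids to scenario and
    truth; when ``outdir`` is given, FASTQ pairs and manifest/truth TSVs
    are written there.
    """
    if not copies:
        raise SimulationError("copies must be non-empty")
    variant = variant or default_spike_variant(panel)
    samples = []
    rows = []
    for li, level in enumerate(copies):
        for ri in range(replicates):
            sid = f"dil_c{level:g}_r{ri + 1}"
            scenario = DilutionScenario(
                variant_id=variant if level > 0 else None,
                variant_copies=float(level),
                wt_copies=wt_copies,
                reads_per_sample=reads_per_sample,
                replicates=replicates,
            )
            rng_seed = _child_seed(seed, 1, li, ri)
            s = simulate_sample(
                panel, scenario, error, seed=rng_seed, sample_id=sid
            )
            s.seed = seed
            samples.append(s)
            rows.append(
                {
                    "sample_id": sid,
                    "level_copies": level,
                    "replicate": ri + 1,
                    "wt_copies": wt_copies,
                    "theoretical_vaf": scenario.theoretical_vaf,
                    "variant": "|".join(map(str, variant)) if level > 0 else "",
                    "realized_templates": (
                        s.truth.variants[0].realized_templates if level > 0 else 0
                    ),
                    "master_seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for s in samples:
            r1 = outdir / f"{s.sample_id}_R1.fastq.gz"
            r2 = outdir / f"{s.sample_id}_R2.fastq.gz"
            s.write(r1, r2)
            paths.append((str(r1), str(r2)))
        manifest["r1"], manifest["r2"] = zip(*paths)
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return samples, manifest


def make_healthy_cohort(
    panel: PanelDefinition,
    n_samples: int = 12,
    reads_per_sample: int = DEFAULT_READS_PER_SAMPLE,
    wt_copies: int = DEFAULT_WT_COPIES,
    error: ErrorModel | None = None,
    seed: int = 0,
) -> list[SimulatedSample]:
    """Variant-free plasma samples (wild-type molecules only, empty truth)."""
    if n_samples < 1:
        raise SimulationError("n_samples must be >= 1")
    samples = []
    for i in range(n_samples):
        scenario = DilutionScenario(
            variant_id=None,
            variant_copies=0.0,
            wt_copies=wt_copies,
            reads_per_sample=reads_per_sample,
        )
        samples.append(
            simulate_sample(
                panel,
                scenario,
                error,
                seed=_child_seed(seed, 2, i),
                sample_id=f"healthy_{i + 1:02d}",
            )
        )
    return samples


def make_matched_tumor(
    panel: PanelDefinition,
    variants: list[tuple[tuple[str, int, str, str], float]],
    error: ErrorModel | None = None,
    seed: int = 0,
    input_copies: int = 5000,
    reads_per_sample: int = DEFAULT_READS_PER_SAMPLE,
    sample_id: str = "tumor",
    tags_per_template: float = DEFAULT_TAGS_PER_TEMPLATE,
    pcr_duplication_mean: float = DEFAULT_PCR_DUPLICATION_MEAN,
) -> SimulatedSample:
    """High-frequency tissue-DNA sample for tumor-confirmation tests.

    Each variant's mutant template count is Binomial(input_copies, freq)
    at its target; an empty variant list behaves as a wild-type sample.
    """
    error = error if error is not None else ErrorModel()
    rng = np.random.default_rng(_child_seed(seed, 3))
    by_target: dict[str, list[tuple[tuple, float]]] = {}
    for vid, freq in variants:
        if not 0.0 < freq <= 1.0:
            raise SimulationError(f"tumor variant frequency {freq} outside (0, 1]")
        by_target.setdefault(vid[0], []).append((vid, freq))

    truth = SampleTruth(sample_id=sample_id)
    spec: dict[str, list] = {}
    planned = []
    for t in panel.targets:
        tid = t.target_id
        entries = []
        wt = input_copies
        for vid, freq in by_target.get(tid, []):
            alt_amp = _validate_variant(panel, vid)
            n_mut = int(rng.binomial(input_copies, freq))
            n_mut = min(n_mut, wt)
            wt -= n_mut
            entries.append((alt_amp, n_mut, ("variant", vid)))
            planned.append((vid, freq, n_mut))
        entries.insert(0, (None, wt, "wt"))
        spec[tid] = entries
        truth.wt_templates[tid] = wt

    pairs, pool, tagged = _simulate_from_templates(
        panel, spec, reads_per_sample, error, rng, sample_id,
        tags_per_template, pcr_duplication_mean,
    )
    for vid, freq, n_mut in planned:
        truth.variants.append(
            TruthVariant(
                variant_id=vid,
                theoretical_vaf=freq,
                realized_templates=n_mut,
                tagged_molecules=tagged.get((vid[0], ("variant", vid)), 0),
                wt_templates=truth.wt_templates[vid[0]],
            )
        )
    return SimulatedSample(sample_id, pairs, truth, pool, seed)
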
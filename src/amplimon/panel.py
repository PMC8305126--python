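"""Multiplex amplicon panel model and primer-design validation.

The panel is a set of genomic regions of interest (breast-cancer hotspot
loci on GRCh38), each amplified by one gene-specific primer pair whose
product is kept short (< 285 bp) so that 2x150 paired-end reads always
overlap. Both primers carry, 5' of the gene-specific part, a 12-nt random
unique molecular identifier (UMI) and, outside that, a fixed universal tag
used downstream as a structural checkpoint.

Printed panel coordinates are 1-based inclusive; BED export converts to
0-based half-open per the UCSC convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .util import chrom_sort_key, hamming, revcomp, seq_to_ints

DEFAULT_UNIVERSAL_TAG = "ACGCTAGCTGATCGGT"  # fixture placeholder, 16 nt
PANEL_COLUMNS = ("gene", "exon", "hotspot", "region")
MAX_PRODUCT_LENGTH = 285

_REGION_RE = re.compile(r"^([A-Za-z0-9_.]+):(\d+)-(\d+)$")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class PanelTarget:
    """One genomic region of interest (1-based inclusive coordinates)."""

    gene: str
    exon: str
    hotspot: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.gene:
            raise PanelError("gene symbol must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise PanelError(
                f"invalid region {self.chrom}:{self.start}-{self.end} for {self.gene}"
            )

    @property
    def target_id(self) -> str:
        return f"{self.gene}_{self.chrom}_{self.start}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint0(self) -> int:
        """0-based floor midpoint of the half-open interval [start-1, end)."""
        return (self.start - 1 + self.end) // 2


@dataclass(frozen=True)
class PrimerPair:
    """Gene-specific primer pair for one target.

    ``product_length`` is the full amplicon length in bp excluding tags and
    UMIs.  ``amplicon_start`` is the 1-based genomic coordinate of the first
    amplicon base (defaults to the target's region start; differs only when
    a region longer than the product cap is covered by a centred amplicon).
    """

    target_id: str
    fwd: str
    rev: str
    product_length: int
    amplicon_start: int = 0

    def __post_init__(self):
        for name, p in (("fwd", self.fwd), ("rev", self.rev)):
            if not 15 <= len(p) <= 40:
                raise PanelError(f"{name} primer length {len(p)} outside [15, 40]")
            seq_to_ints(p)  # rejects ambiguous bases
        if not self.product_length < MAX_PRODUCT_LENGTH:
            raise PanelError(
                f"product_length {self.product_length} >= {MAX_PRODUCT_LENGTH}"
            )
        if self.product_length < len(self.fwd) + len(self.rev) + 1:
            raise PanelError("product shorter than its two primers")


@dataclass(frozen=True)
class LibraryStructure:
    """Library layout outside the gene-specific primers: tag + UMI."""

    universal_tag: str = DEFAULT_UNIVERSAL_TAG
    umi_length: int = 12

    def __post_init__(self):
        if len(self.universal_tag) < 10:
            raise PanelError("universal tag must be at least 10 nt")
        if self.umi_length < 1:
            raise PanelError("umi_length must be positive")


@dataclass
class PanelDefinition:
    """Targets, primers, library layout and amplicon reference sequences."""

    targets: list[PanelTarget]
    primers: list[PrimerPair] = field(default_factory=list)
    library: LibraryStructure = field(default_factory=LibraryStructure)
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for t in self.targets:
            key = (t.chrom, t.start, t.end)
            if key in seen:
                raise PanelError(f"duplicate region {t.chrom}:{t.start}-{t.end}")
            seen.add(key)
        self.validate()

    # -- lookups ---------------------------------------------------------
    def target(self, target_id: str) -> PanelTarget:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(target_id)

    def primer_for(self, target_id: str) -> PrimerPair:
        for p in self.primers:
            if p.target_id == target_id:
                return p
        raise KeyError(target_id)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def genes(self) -> list[str]:
        return sorted({t.gene for t in self.targets})

    def validate(self) -> None:
        ids = {t.target_id for t in self.targets}
        for p in self.primers:
            if p.target_id not in ids:
                raise PanelError(f"primer references unknown target {p.target_id}")
            ref = self.reference.get(p.target_id)
            if ref is not None and len(ref) != p.product_length:
                raise PanelError(
                    f"reference length {len(ref)} != product_length "
                    f"{p.product_length} for {p.target_id}"
                )

    def subset(self, target_ids: Sequence[str]) -> "PanelDefinition":
        keep = set(target_ids)
        missing = keep - {t.target_id for t in self.targets}
        if missing:
            raise KeyError(f"unknown targets: {sorted(missing)}")
        return PanelDefinition(
            targets=[t for t in self.targets if t.target_id in keep],
            primers=[p for p in self.primers if p.target_id in keep],
            library=self.library,
            reference={k: v for k, v in self.reference.items() if k in keep},
        )

    def to_tsv(self) -> str:
        lines = ["\t".join(PANEL_COLUMNS)]
        for t in self.targets:
            lines.append(
                f"{t.gene}\t{t.exon}\t{t.hotspot}\t{t.chrom}:{t.start}-{t.end}"
            )
        return "\n".join(lines) + "\n"


def parse_region(text: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(text.strip())
    if not m:
        raise PanelError(f"malformed region string {text!r} (expected chrom:start-end)")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    return chrom, start, end


def load_panel(path) -> PanelDefinition:
    """Load a panel TSV (columns gene, exon, hotspot, region).

    Fails atomically: any malformed row raises PanelError naming the row and
    no partial panel is returned.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel file {path} missing columns {missing}")
    targets = []
    for i, row in df.iterrows():
        try:
            chrom, start, end = parse_region(row["region"])
            targets.append(
                PanelTarget(
                    gene=row["gene"].strip(),
                    exon=row["exon"].strip(),
                    hotspot=row["hotspot"].strip(),
                    chrom=chrom,
                    start=start,
                    end=end,
                )
            )
        except PanelError as exc:
            raise PanelError(f"row {i + 2} of {path}: {exc}") from exc
    return PanelDefinition(targets=targets)


def bundled_panel_path():
    """Path to the bundled breast-cancer hotspot panel table."""
    return resources.files("amplimon.data") / "panel_breast38.tsv"


def load_bundled_panel() -> PanelDefinition:
    with resources.as_file(bundled_panel_path()) as p:
        return load_panel(p)


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def _sorted_targets(panel: PanelDefinition) -> list[PanelTarget]:
    return sorted(panel.targets, key=lambda t: (chrom_sort_key(t.chrom), t.start))


def export_bed(panel: PanelDefinition) -> str:
    """Targets as 3-column BED (0-based half-open), sorted by chrom, start."""
    lines = [f"{t.chrom}\t{t.start - 1}\t{t.end}" for t in _sorted_targets(panel)]
    return "\n".join(lines) + ("\n" if lines else "")


def midpoint_bed(panel: PanelDefinition) -> str:
    """1-bp BED intervals at the floor midpoint of each target region."""
    lines = []
    for t in _sorted_targets(panel):
        m = t.midpoint0
        lines.append(f"{t.chrom}\t{m}\t{m + 1}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Primer checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSite:
    ref_name: str
    strand: str  # "+" or "-"
    offset: int  # 0-based window start on the given strand orientation
    distance: int


@dataclass
class UniquenessReport:
    primer: str
    min_hamming: int
    sites: list[BindingSite]

    @property
    def passed(self) -> bool:
        return len(self.sites) == 1 and self.sites[0].distance == 0


def _scan_strand(primer_arr: np.ndarray, ref_arr: np.ndarray, max_dist: int):
    """All window offsets with Hamming distance < max_dist (vectorised)."""
    k, n = primer_arr.size, ref_arr.size
    if n < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, k)
    dists = (windows != primer_arr).sum(axis=1)
    hits = np.nonzero(dists < max_dist)[0]
    return [(int(o), int(dists[o])) for o in hits]


def check_primer_uniqueness(
    primer: str,
    references: Mapping[str, str] | Iterable[str],
    min_hamming: int = 3,
) -> UniquenessReport:
    """Scan every window of every reference (both strands) for near-matches.

    A primer passes when exactly one binding site exists with Hamming
    distance below ``min_hamming`` (the intended site, at distance 0); a
    second site at distance exactly ``min_hamming`` is tolerated, matching a
    minimum-distance-3, mismatch-only design rule.
    """
    primer_arr = seq_to_ints(primer)  # raises on ambiguous bases
    if isinstance(references, Mapping):
        items = list(references.items())
    else:
        items = [(f"ref{i}", s) for i, s in enumerate(references)]
    sites: list[BindingSite] = []
    for name, ref in items:
        if len(primer) > len(ref):
            raise PanelError(
                f"primer longer than reference {name} ({len(primer)} > {len(ref)})"
            )
        fwd_arr = seq_to_ints(ref)
        for off, d in _scan_strand(primer_arr, fwd_arr, min_hamming):
            sites.append(BindingSite(name, "+", off, d))
        rev_arr = seq_to_ints(revcomp(ref))
        for off, d in _scan_strand(primer_arr, rev_arr, min_hamming):
            sites.append(BindingSite(name, "-", off, d))
    return UniquenessReport(primer=primer, min_hamming=min_hamming, sites=sites)


@dataclass(frozen=True)
class DimerHit:
    name_a: str
    name_b: str
    run: int  # longest 3'-anchored reverse-complement run of a against b


@dataclass
class DimerReport:
    max_3prime_complement: int
    runs: dict[tuple[str, str], int]
    flagged: list[DimerHit]


def _three_prime_run(a: str, b: str) -> int:
    """Longest suffix of ``a`` whose reverse complement occurs in ``b``."""
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if revcomp(a[-k:]) in b:
            best = k
        else:
            break  # a longer suffix contains this one; no need to continue
    return best


def check_cross_dimers(
    primers: Sequence[PrimerPair] | Sequence[tuple[str, str]],
    max_3prime_complement: int = 5,
) -> DimerReport:
    """3'-anchored cross-dimer screen over every ordered primer pair.

    For ordered pair (a, b) the score is the longest perfect
    reverse-complement run ending at a's 3' terminus that can anneal to b
    (self-pairs included). Pairs with run > ``max_3prime_complement`` are
    flagged.  This is a perfect-complementarity screen, not a thermodynamic
    one; see the methods note.
    """
    if not primers:
        raise PanelError("need at least one primer")
    named: list[tuple[str, str]] = []
    for item in primers:
        if isinstance(item, PrimerPair):
            named.append((f"{item.target_id}_fwd", item.fwd))
            named.append((f"{item.target_id}_rev", item.rev))
        else:
            named.append((item[0], item[1]))
    runs: dict[tuple[str, str], int] = {}
    flagged: list[DimerHit] = []
    for name_a, a in named:
        for name_b, b in named:
            r = _three_prime_run(a, b)
            runs[(name_a, name_b)] = r
            if r > max_3prime_complement:
                flagged.append(DimerHit(name_a, name_b, r))
    return DimerReport(max_3prime_complement, runs, flagged)


@dataclass
class HairpinReport:
    primer: str
    min_stem: int
    stem: int
    loop: int
    stem5_start: int
    stem3_start: int

    @property
    def flagged(self) -> bool:
        return self.stem >= self.min_stem


def check_hairpin(primer: str, min_stem: int = 6) -> HairpinReport:
    """Longest self-complementary stem with loop >= 3 nt, brute force.

    Requires len(primer) >= 2*min_stem + 3 so that a reportable hairpin can
    exist at all.
    """
    n = len(primer)
    if n < 2 * min_stem + 3:
        raise PanelError(
            f"primer length {n} < 2*min_stem+3 = {2 * min_stem + 3}"
        )
    best = (0, 0, 0, 0)  # stem, loop, i, j
    for s in range(1, n // 2 + 1):
        for i in range(0, n - 2 * s - 3 + 1):
            for j in range(i + s + 3, n - s + 1):
                if primer[i : i + s] == revcomp(primer[j : j + s]):
                    loop = j - (i + s)
                    if s > best[0]:
                        best = (s, loop, i, j)
    stem, loop, i, j = best
    return HairpinReport(primer, min_stem, stem, loop, i, j)
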
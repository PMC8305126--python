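"""Four-level read filtering for dual-UMI amplicon libraries.

Levels, applied strictly in order (each level only sees survivors of the
previous one):

1. quality gate  -- at most 30 bases below Q28, counted jointly over both
   mates of a pair (10% of the 300-bp maximum pair length);
2. perfect merge -- R1 and reverse-complemented R2 must share a unique,
   zero-mismatch overlap (>= 15 nt); the pair is assembled into one
   sequence, taking the per-position maximum quality in the overlap;
   tag check     -- both ends of the assembled read must show the universal
   tag with at most 2 mismatches (applied between levels 2 and 3);
3. primer trim   -- the 12-nt UMIs are read off both ends, then the read
   must match exactly one panel primer pair with at most 3 mismatches per
   primer (end-anchored, ungapped); primers are trimmed and the read is
   assigned to that target;
4. UMI dedup     -- reads are clustered by exact (target, UMI5, UMI3) key
   and every cluster with more than one read is discarded outright, which
   removes all possible PCR duplicates without consensus-building.

All comparisons are end-anchored ungapped mismatch counts (no indels),
which makes every step reproducible against a brute-force oracle.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import PanelDefinition
from .util import decode_phred, encode_phred, hamming, revcomp


@dataclass
class ReadPair:
    """One raw paired-end read (qualities as integer Phred arrays)."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray

    def __post_init__(self):
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(
            self.r2_qual
        ):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


@dataclass
class MergedRead:
    """Assembled read pair; tags/UMIs/primers are stripped step by step."""

    id: str
    seq: str
    qual: np.ndarray
    umi5: str = ""
    umi3: str = ""
    target_id: str = ""
    trimmed: bool = False


@dataclass
class FilterStats:
    """Per-level removal accounting; input = survivors + sum(removed)."""

    input_pairs: int = 0
    removed_level1: int = 0
    removed_level2: int = 0
    removed_tagcheck: int = 0
    removed_level3: int = 0
    removed_level4_reads: int = 0
    survivors: int = 0

    def check_conservation(self) -> bool:
        return self.input_pairs == (
            self.survivors
            + self.removed_level1
            + self.removed_level2
            + self.removed_tagcheck
            + self.removed_level3
            + self.removed_level4_reads
        )

    def fractions(self) -> dict[str, float]:
        n = max(self.input_pairs, 1)
        return {
            "level1_quality": self.removed_level1 / n,
            "level2_merge": self.removed_level2 / n,
            "tag_check": self.removed_tagcheck / n,
            "level3_primer": self.removed_level3 / n,
            "level4_dedup": self.removed_level4_reads / n,
            "survivors": self.survivors / n,
        }

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["fractions"] = self.fractions()
        return json.dumps(d, indent=2)

    def to_tsv(self) -> str:
        rows = ["metric\tcount"]
        rows += [f"{k}\t{v}" for k, v in self.__dict__.items()]
        return "\n".join(rows) + "\n"


@dataclass
class FilterConfig:
    max_low_bases: int = 30
    q_threshold: int = 28
    min_overlap: int = 15
    tag_max_deviation: int = 2
    primer_max_hamming: int = 3
    umi_length: int = 12


# ---------------------------------------------------------------------------
# Level 1: quality gate
# ---------------------------------------------------------------------------

def filter_quality(
    pair: ReadPair, max_low_bases: int = 30, q_threshold: int = 28
) -> bool:
    """Pass iff the pair has at most ``max_low_bases`` bases below
    ``q_threshold``, counted over both mates jointly."""
    low = int((pair.r1_qual < q_threshold).sum()) + int(
        (pair.r2_qual < q_threshold).sum()
    )
    return low <= max_low_bases


# ---------------------------------------------------------------------------
# Level 2: perfect-overlap assembly
# ---------------------------------------------------------------------------

def merge_pair(pair: ReadPair, min_overlap: int = 15) -> MergedRead | None:
    """Assemble a pair via its unique zero-mismatch overlap, else reject.

    The overlap is searched between R1 and the reverse complement of R2.
    Rejection (None) occurs when no zero-mismatch overlap of at least
    ``min_overlap`` exists, or when more than one distinct overlap length
    matches perfectly (ambiguous assembly).  Overlap qualities take the
    per-position maximum of the two mates.
    """
    r1, q1 = pair.r1_seq, pair.r1_qual
    rc2 = revcomp(pair.r2_seq)
    q2 = pair.r2_qual[::-1]
    l1, l2 = len(r1), len(rc2)
    if min(l1, l2) < min_overlap:
        return None
    seed = rc2[:min_overlap]
    overlaps = []
    start = 0
    while True:
        p = r1.find(seed, start)
        if p == -1 or p > l1 - min_overlap:
            break
        ov = l1 - p
        if ov <= l2 and r1[p:] == rc2[:ov]:
            overlaps.append(ov)
        start = p + 1
    if len(overlaps) != 1:
        return None
    ov = overlaps[0]
    p = l1 - ov
    seq = r1 + rc2[ov:]
    qual = np.concatenate([q1[:p], np.maximum(q1[p:], q2[:ov]), q2[ov:]])
    return MergedRead(id=pair.id, seq=seq, qual=qual)


# ---------------------------------------------------------------------------
# Tag check (between levels 2 and 3)
# ---------------------------------------------------------------------------

def check_tags(
    m: MergedRead, tag: str, max_deviation: int = 2, umi_length: int = 12
) -> MergedRead | None:
    """Verify and strip the universal tag at both ends (<= 2 mismatches each).

    The 5' prefix is compared to the tag and the 3' suffix to its reverse
    complement, by ungapped mismatch count.  Reads too short to contain two
    tags plus two UMIs fail the check.
    """
    lt = len(tag)
    if len(m.seq) < 2 * lt + 2 * umi_length:
        return None
    if hamming(m.seq[:lt], tag) > max_deviation:
        return None
    if hamming(m.seq[-lt:], revcomp(tag)) > max_deviation:
        return None
    return MergedRead(
        id=m.id,
        seq=m.seq[lt:-lt],
        qual=m.qual[lt:-lt],
        umi5=m.umi5,
        umi3=m.umi3,
        target_id=m.target_id,
        trimmed=m.trimmed,
    )


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------

def extract_umis(
    m: MergedRead, umi_length: int = 12, min_insert: int = 1
) -> MergedRead | None:
    """Read off the 5' UMI and the (reverse-complemented) 3' UMI.

    Both UMIs are removed from the sequence; umi3 is stored in the
    orientation in which it was synthesised on the reverse primer.
    """
    if len(m.seq) < 2 * umi_length + min_insert:
        return None
    umi5 = m.seq[:umi_length]
    umi3 = revcomp(m.seq[-umi_length:])
    return MergedRead(
        id=m.id,
        seq=m.seq[umi_length:-umi_length],
        qual=m.qual[umi_length:-umi_length],
        umi5=umi5,
        umi3=umi3,
        target_id=m.target_id,
        trimmed=m.trimmed,
    )


# ---------------------------------------------------------------------------
# Level 3: primer trimming / unique target assignment
# ---------------------------------------------------------------------------

def _primer_table(panel: PanelDefinition) -> list[tuple[str, str, str]]:
    return [(p.target_id, p.fwd, revcomp(p.rev)) for p in panel.primers]


def _match_primers(
    m: MergedRead,
    table: Sequence[tuple[str, str, str]],
    max_hamming: int,
) -> MergedRead | None:
    matches = []
    for target_id, fwd, rcrev in table:
        lf, lr = len(fwd), len(rcrev)
        if len(m.seq) < lf + lr + 1:
            continue
        if hamming(m.seq[:lf], fwd) > max_hamming:
            continue
        if hamming(m.seq[-lr:], rcrev) > max_hamming:
            continue
        matches.append((target_id, lf, lr))
    if len(matches) != 1:
        return None  # unassigned or ambiguous: unique-assignment contract
    target_id, lf, lr = matches[0]
    return MergedRead(
        id=m.id,
        seq=m.seq[lf:-lr],
        qual=m.qual[lf:-lr],
        umi5=m.umi5,
        umi3=m.umi3,
        target_id=target_id,
        trimmed=True,
    )


def trim_primers(
    m: MergedRead, panel: PanelDefinition, max_hamming: int = 3
) -> MergedRead | None:
    """Assign the read to the unique primer pair matching both ends.

    Both the 5' prefix (vs forward primer) and the 3' suffix (vs reverse
    complement of the reverse primer) must be within ``max_hamming``
    mismatches; zero or multiple qualifying primer pairs reject the read.
    """
    return _match_primers(m, _primer_table(panel), max_hamming)


# ---------------------------------------------------------------------------
# Level 4: UMI deduplication
# ---------------------------------------------------------------------------

def dedup_umi(
    reads: Iterable[MergedRead],
) -> tuple[list[MergedRead], Counter]:
    """Discard every (target, UMI5, UMI3) cluster with more than one read.

    Returns the surviving reads in deterministic (sorted-key) order and a
    histogram of cluster sizes.  Running the operation on its own output is
    the identity.
    """
    clusters: dict[tuple[str, str, str], list[MergedRead]] = {}
    for r in reads:
        clusters.setdefault((r.target_id, r.umi5, r.umi3), []).append(r)
    histogram = Counter(len(v) for v in clusters.values())
    survivors = [
        members[0]
        for key, members in sorted(clusters.items())
        if len(members) == 1
    ]
    return survivors, histogram


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two (optionally gzipped) FASTQs."""
    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        def base_id(title: str) -> str:
            name = title.split()[0]
            if name.endswith(("/1", "/2")):
                name = name[:-2]
            return name

        for rec1, rec2 in zip(it1, it2, strict=True):
            id1 = base_id(rec1[0])
            id2 = base_id(rec2[0])
            if id1 != id2:
                raise RuntimeError(
                    f"desynchronized FASTQ mates: {rec1[0]!r} vs {rec2[0]!r}"
                )
            yield ReadPair(
                id=id1,
                r1_seq=rec1[1],
                r2_seq=rec2[1],
                r1_qual=decode_phred(rec1[2]),
                r2_qual=decode_phred(rec2[2]),
            )


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    """Write mates to gzipped Phred+33 FASTQ (mtime pinned for determinism)."""
    with open(r1_path, "wb") as raw1, open(r2_path, "wb") as raw2:
        with gzip.GzipFile(
            filename="", fileobj=raw1, mode="wb", mtime=0
        ) as f1, gzip.GzipFile(
            filename="", fileobj=raw2, mode="wb", mtime=0
        ) as f2:
            for p in pairs:
                f1.write(
                    f"@{p.id}\n{p.r1_seq}\n+\n{encode_phred(p.r1_qual)}\n".encode()
                )
                f2.write(
                    f"@{p.id}\n{p.r2_seq}\n+\n{encode_phred(p.r2_qual)}\n".encode()
                )


# ---------------------------------------------------------------------------
# Full stack
# ---------------------------------------------------------------------------

def run_filter_stack(
    source,
    panel: PanelDefinition,
    config: FilterConfig | None = None,
) -> tuple[list[MergedRead], FilterStats]:
    """Apply levels 1 -> 2 -> tag check -> 3 -> 4 in order.

    ``source`` may be an iterable of ReadPair, an object with a ``pairs``
    attribute (a simulated sample), or an (r1_path, r2_path) tuple of FASTQ
    files.  Returns deduplicated, trimmed, target-assigned reads plus the
    per-level accounting, which always conserves the input count.
    """
    cfg = config or FilterConfig()
    if isinstance(source, tuple) and len(source) == 2:
        pairs: Iterable[ReadPair] = iter_fastq_pairs(*source)
    elif hasattr(source, "pairs"):
        pairs = source.pairs
    else:
        pairs = source

    tag = panel.library.universal_tag
    table = _primer_table(panel)
    stats = FilterStats()
    assigned: list[MergedRead] = []
    for pair in pairs:
        stats.input_pairs += 1
        if not filter_quality(pair, cfg.max_low_bases, cfg.q_threshold):
            stats.removed_level1 += 1
            continue
        merged = merge_pair(pair, cfg.min_overlap)
        if merged is None:
            stats.removed_level2 += 1
            continue
        tagged = check_tags(merged, tag, cfg.tag_max_deviation, cfg.umi_length)
        if tagged is None:
            stats.removed_tagcheck += 1
            continue
        with_umis = extract_umis(tagged, cfg.umi_length)
        if with_umis is None:
            stats.removed_level3 += 1
            continue
        trimmed = _match_primers(with_umis, table, cfg.primer_max_hamming)
        if trimmed is None:
            stats.removed_level3 += 1
            continue
        assigned.append(trimmed)
    survivors, _histogram = dedup_umi(assigned)
    stats.removed_level4_reads = len(assigned) - len(survivors)
    stats.survivors = len(survivors)
    return survivors, stats
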
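import numpy as np
import pytest

from amplimon.panel import (
    LibraryStructure,
    PanelDefinition,
    PanelTarget,
)
from amplimon.readfilter import ReadPair
from amplimon.simulate import (
    default_panel,
    default_spike_variant,
    make_fixture_primers,
    make_reference,
)
from amplimon.util import revcomp


@pytest.fixture(scope="session")
def full_panel():
    """Bundled 21-target panel with fixture primers and references."""
    return default_panel()


@pytest.fixture(scope="session")
def spike_variant(full_panel):
    return default_spike_variant(full_panel)


@pytest.fixture(scope="session")
def mini_panel():
    """Two small targets with deterministic fixture primers/references."""
    targets = [
        PanelTarget(gene="GENEA", exon="1. exon", hotspot="X1",
                    chrom="1", start=101, end=220),
        PanelTarget(gene="GENEB", exon="2. exon", hotspot="X2",
                    chrom="2", start=501, end=600),
    ]
    p = PanelDefinition(targets=targets, library=LibraryStructure())
    p.primers = make_fixture_primers(p, seed=11)
    make_reference(p, seed=12)
    return p


def construct_for(panel, target_id, umi5="A" * 12, umi3="C" * 12, variant=None):
    """Full library construct: tag + UMI5 + amplicon + rc(UMI3) + rc(tag)."""
    amp = panel.reference[target_id]
    if variant is not None:
        _, pos, ref, alt = variant
        assert amp[pos - 1] == ref
        amp = amp[: pos - 1] + alt + amp[pos:]
    tag = panel.library.universal_tag
    return tag + umi5 + amp + revcomp(umi3) + revcomp(tag)


def pair_from_construct(construct, q=40, read_id="r", read_length=150):
    """Error-free 2x150 pair as the simulator would emit it."""
    rl = min(read_length, len(construct))
    r1 = construct[:rl]
    r2 = revcomp(construct)[:rl]
    return ReadPair(
        id=read_id,
        r1_seq=r1,
        r2_seq=r2,
        r1_qual=np.full(rl, q, dtype=np.int16),
        r2_qual=np.full(rl, q, dtype=np.int16),
    )


def mutate(seq: str, pos0: int) -> str:
    """Substitute the base at pos0 with a different one (cyclic A->C->G->T)."""
    order = "ACGT"
    new = order[(order.index(seq[pos0]) + 1) % 4]
    return seq[:pos0] + new + seq[pos0 + 1:]
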
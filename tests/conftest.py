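"""Shared fixtures: a hand-built CAGCC locus and its illustrative reads."""

import pytest

from ssrtally.panel import LocusDefinition, MotifSpec, Panel

# 20-bp flanks around a 3-copy CAGCC array.  The right flank starts CAGCT so
# that a single T->C change in it creates a spurious fourth motif copy.
FLANK_L = "GATTACAGATTACAGATTAG"
FLANK_R = "CAGCTTGACCTGACTTGACG"


@pytest.fixture(scope="session")
def cagcc_locus() -> LocusDefinition:
    ref = FLANK_L + "CAGCC" * 3 + FLANK_R
    return LocusDefinition("demoL", ref, MotifSpec("CAGCC"), 20, 35)


@pytest.fixture(scope="session")
def cagcc_panel(cagcc_locus) -> Panel:
    return Panel.from_loci([cagcc_locus])


@pytest.fixture(scope="session")
def seq1(cagcc_locus) -> str:
    """Reference-identical read: three exact CAGCC copies."""
    return cagcc_locus.ref_seq


@pytest.fixture(scope="session")
def seq2(cagcc_locus) -> str:
    """One substitution (G->A) inside the first SSR copy."""
    ref = cagcc_locus.ref_seq
    pos = cagcc_locus.ssr_start + 2  # the G of the first CAGCC
    assert ref[pos] == "G"
    return ref[:pos] + "A" + ref[pos + 1 :]


@pytest.fixture(scope="session")
def seq3(cagcc_locus) -> str:
    """T->C in the right flank, creating a spurious fourth copy."""
    ref = cagcc_locus.ref_seq
    pos = cagcc_locus.ssr_end + 4  # the T of flank-initial CAGCT
    assert ref[pos] == "T"
    return ref[:pos] + "C" + ref[pos + 1 :]
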
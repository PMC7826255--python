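"""Shared fixtures: deterministic amplicons and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from editrace.core import Amplicon, revcomp
from editrace.simulate import random_amplicon


def build_amplicon(
    length: int = 140,
    seed: int = 0,
    edits: dict[int, str] | None = None,
    amplicon_id: str = "test_amp",
) -> Amplicon:
    """A random but deterministic + strand amplicon with optional base pins.

    ``edits`` maps reference positions to forced bases (applied before
    the PAM is stamped, and may override it if they hit its positions).
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    cut = length // 2
    pam_start = cut + 3
    seq[pam_start + 1 : pam_start + 3] = "GG"
    for pos, base in (edits or {}).items():
        seq[pos] = base
    ref = "".join(seq)
    return Amplicon(
        id=amplicon_id,
        reference_sequence=ref,
        protospacer=ref[pam_start - 20 : pam_start],
        pam_start=pam_start,
        strand="+",
    )


def mirror_amplicon(amplicon: Amplicon) -> Amplicon:
    """The same locus stored on the opposite reference strand."""
    ref = revcomp(amplicon.reference_sequence)
    length = len(ref)
    return Amplicon(
        id=amplicon.id + "_rc",
        reference_sequence=ref,
        protospacer=amplicon.protospacer,
        pam_start=length - amplicon.pam_start - 3,
        strand="-" if amplicon.strand == "+" else "+",
    )


@pytest.fixture
def amp_t(scope="session") -> Amplicon:
    """Amplicon with T at the -4 position (cut at 70)."""
    return build_amplicon(edits={69: "T", 70: "A"})


@pytest.fixture
def amp_gg() -> Amplicon:
    """Amplicon with G|G across the cut site."""
    return build_amplicon(edits={69: "G", 70: "G"}, amplicon_id="gg_amp")


@pytest.fixture
def amp_tt() -> Amplicon:
    """Amplicon with T|T across the cut site."""
    return build_amplicon(edits={69: "T", 70: "T"}, amplicon_id="tt_amp")


@pytest.fixture
def sim_amp() -> Amplicon:
    return random_amplicon(11, minus4="T", amplicon_id="sim11")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
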
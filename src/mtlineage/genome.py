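"""Coordinate conventions and variant-id helpers for the mitochondrial genome.

Mitochondrial positions are 1-based inclusive (so variant ids read like
``7161G>A``); nuclear fragment/bin coordinates elsewhere in the package follow
the BED convention (0-based, half-open).
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np

#: Length of the human mitochondrial genome (rCRS numbering).
MT_GENOME_LENGTH = 16569

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_VARIANT_RE = re.compile(r"^(\d+)([ACGT])>([ACGT])$")


@lru_cache(maxsize=1)
def synthetic_reference() -> np.ndarray:
    """Return a synthetic stand-in mtDNA reference sequence.

    One base per position 1..16,569, drawn from a fixed pseudo-random stream so
    the sequence is identical across processes.  This is *not* the rCRS: the
    simulator and the count tensor only need a consistent REF base per
    position, never the true sequence.  Index 0 of the returned array
    corresponds to position 1.
    """
    rng = np.random.default_rng(16569)
    return rng.choice(np.array(BASES), size=MT_GENOME_LENGTH)


def variant_id(pos: int, ref: str, alt: str) -> str:
    """Format a variant as ``<pos><REF>><ALT>``, e.g. ``7161G>A``."""
    if ref == alt:
        raise ValueError(f"REF equals ALT ({ref}) at position {pos}")
    return f"{pos}{ref}>{alt}"


def parse_variant_id(vid: str) -> tuple[int, str, str]:
    """Parse ``7161G>A`` into ``(7161, 'G', 'A')``.

    Raises ``ValueError`` for malformed ids, REF==ALT, or positions outside
    the mitochondrial genome.
    """
    m = _VARIANT_RE.match(vid)
    if m is None:
        raise ValueError(f"malformed variant id: {vid!r}")
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    if not 1 <= pos <= MT_GENOME_LENGTH:
        raise ValueError(f"position {pos} outside mtDNA genome (1..{MT_GENOME_LENGTH})")
    if ref == alt:
        raise ValueError(f"REF equals ALT in variant id {vid!r}")
    return pos, ref, alt
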
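"""Named random substreams.

All randomness in the pipeline flows from integer seeds through named
substreams, so that e.g. the pattern noise of a session and its probe
draws are independent streams that reproduce bit-for-bit given the seed.
"""

from __future__ import annotations

import zlib

import numpy as np

CHEATING = "cheating"
PARANOID = "paranoid"
GROUPS = (CHEATING, PARANOID)


def group_sign(group: str) -> int:
    """+1 for the cheating interpretation, -1 for paranoid."""
    if group == CHEATING:
        return 1
    if group == PARANOID:
        return -1
    raise ValueError(f"unknown group label: {group!r}")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so distinct names give
    independent, reproducible streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
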
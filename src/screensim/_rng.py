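"""Seeded random-number substreams.

Each module draws from its own child stream derived from the master
seed, so adding a module (or reordering draws inside one) does not
perturb the streams used by the others.  Streams are keyed by a string
label hashed onto the master ``SeedSequence``.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _label_entropy(label: str) -> int:
    digest = hashlib.sha256(label.encode()).digest()
    return int.from_bytes(digest[:8], "little")


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Independent generator for ``label`` under ``master_seed``."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, _label_entropy(label)])
    return np.random.default_rng(ss)


def child_seed(master_seed: int, label: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(substream(master_seed, label).integers(0, 2**31))
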
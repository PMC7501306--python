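"""Seed-stream derivation.

One root seed drives the whole pipeline; each stage draws from its own child
stream so that, e.g., regenerating the gene-set collection does not perturb
the per-cell assay tables. Streams are derived from a stable CRC32 of a text
label, so the mapping seed -> stream is independent of call order.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for `label`'s stream under the given root seed."""
    if seed is None:
        raise ValueError("a root seed is required for reproducibility")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
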
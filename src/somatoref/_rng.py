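"""Seed plumbing: named, independent substreams from one master seed.

Every stochastic stage of the pipeline derives its generator with
``substream(master_seed, "stage", ...)`` so that stages (and the three
somatosensory measures within a stage) are independently reproducible:
rerunning one stage with the same master seed gives the same draws no
matter what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_hash(keys: tuple) -> int:
    joined = "\x1f".join(str(k) for k in keys)
    return zlib.crc32(joined.encode("utf-8"))


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``.

    Distinct key tuples yield statistically independent streams; the same
    (master_seed, keys) pair always yields the same stream.
    """
    if not (0 <= int(master_seed) < 2**63):
        raise ValueError(f"master seed out of range: {master_seed}")
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(_key_hash(keys),))
    return np.random.default_rng(ss)
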
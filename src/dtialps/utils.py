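"""Small shared helpers."""

from __future__ import annotations

import zlib

#: seeds handed to numpy generators are kept below 2**31
_SEED_MOD = 2**31


def derive_seed(seed: int, label: str) -> int:
    """Derive a stable per-stage seed from a base seed and a stage label.

    Uses CRC32 of the label so every stage of a run draws from an
    independent stream while the whole run stays reproducible from one seed.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode())) % _SEED_MOD
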
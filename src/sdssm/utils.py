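"""Small shared helpers (seed-stream derivation)."""

from __future__ import annotations

import zlib

__all__ = ["seed_stream"]


def seed_stream(root_seed: int, name: str, index: int = 0) -> int:
    """Derive a reproducible sub-seed < 2^31 from one root seed.

    One root seed governs parameter initialization, data shuffling and all
    reparameterization noise through named streams, so separate consumers of
    randomness stay decoupled but fully reproducible.
    """
    tag = f"{int(root_seed)}:{name}:{int(index)}".encode()
    return zlib.crc32(tag) & 0x7FFFFFFF
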
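"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *keys) -> int:
    """Deterministically derive a child seed (< 2**31) from a master seed.

    Stage names and replicate indices are hashed so that stages draw
    independent streams while the whole pipeline stays reproducible from one
    master seed.
    """
    material = repr((int(master),) + tuple(keys)).encode()
    digest = hashlib.sha256(material).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
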
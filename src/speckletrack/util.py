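"""Seed plumbing: every source of randomness derives from one master seed."""

from __future__ import annotations

import hashlib


def substream_seed(master: int, *labels: object) -> int:
    """Derive a reproducible child seed < 2**31 from a master seed and labels.

    Named substreams ("screen", "noise", "scene", ...) let components be
    re-seeded independently while staying deterministic end to end.
    """
    tag = f"{int(master)}:" + ":".join(str(l) for l in labels)
    digest = hashlib.blake2b(tag.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
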
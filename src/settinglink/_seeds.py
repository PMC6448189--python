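"""Deterministic seed derivation.

All randomness in the package flows from one root seed.  Stage and
per-setting seeds are derived by hashing ``(root, *labels)`` so that adding
a stage or a setting never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31


def derive_seed(root: int, *labels: object) -> int:
    """Derive a sub-seed in ``[0, 2**31)`` from a root seed and labels."""
    key = ":".join([str(int(root)), *(str(x) for x in labels)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
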
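"""Named random-number streams derived from a single master seed.

Every stochastic component of the package pulls its generator from
:func:`stream`, keyed by a component name, so that any one component is
reproducible in isolation and adding a new consumer never perturbs the
draws of an existing one.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream"]


def _name_key(names: tuple) -> int:
    digest = hashlib.sha256("/".join(str(n) for n in names).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def stream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the stream identified by ``names``.

    The stream depends only on ``seed`` and the name tuple, never on how
    many other streams have been created.
    """
    base = int(seed) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([base, _name_key(names)]))
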
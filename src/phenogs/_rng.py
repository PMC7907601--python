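"""Named random substreams derived from one root seed.

Every stochastic stage draws from its own child of the root
``SeedSequence`` so that, e.g., regenerating the field layout does not
perturb the marker data.  Stream names map to fixed spawn keys, making
each stage independently reproducible.
"""

from __future__ import annotations

import numpy as np

# fixed registry: changing an id silently changes downstream draws
_STREAMS = {
    "genotypes": 0,
    "effects": 1,
    "residuals": 2,
    "layout": 3,
    "reflectance": 4,
    "cv": 5,
    "misc": 6,
}


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``root_seed``."""
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(
            f"unknown stream {name!r}; known: {sorted(_STREAMS)}"
        ) from None
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def replicate_stream(root_seed: int, name: str, replicate: int) -> np.random.Generator:
    """A per-replicate child stream (used by cross-validation)."""
    key = _STREAMS[name]
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(key, int(replicate)))
    return np.random.default_rng(ss)
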
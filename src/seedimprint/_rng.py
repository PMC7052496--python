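"""Named, independent random substreams derived from one master seed.

Each component of the simulator draws from its own stream so that, e.g.,
adding genes to the count simulation does not perturb the allele-count
draws. Streams are keyed by a stable CRC32 of their name.
"""

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` under `master_seed`."""
    key = zlib.crc32(name.encode("utf8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return np.random.Generator(np.random.PCG64(ss))


def child_seed(master_seed: int, name: str) -> int:
    """A deterministic 31-bit integer seed for `name` (for libraries that
    take plain int seeds, e.g. scikit-learn)."""
    return int(substream(master_seed, name).integers(0, 2**31 - 1))
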
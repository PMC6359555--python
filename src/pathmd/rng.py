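"""Named child RNG streams derived from one master seed.

Every stochastic component of a run (thermostat noise, coupling-xi draws,
adaptive-bias zeta draws, fixture generation) pulls from its own
independent stream so that switching one component on or off never shifts
the random numbers seen by the others.  This is what makes the
unbiased-limit bit-equivalence contract testable: with the bias couplings
at zero, the thermostat stream is consumed identically whether or not the
bias stack is attached.
"""

from __future__ import annotations

import numpy as np

# Stable stream indices; order is part of the reproducibility contract.
STREAMS = {
    "thermostat": 0,
    "coupling": 1,
    "adaptive": 2,
    "fixtures": 3,
    "analysis": 4,
}


def child_rng(master_seed: int, stream: str) -> np.random.Generator:
    """Return the named child generator for ``master_seed``.

    Parameters
    ----------
    master_seed:
        Non-negative integer master seed of the run.
    stream:
        One of ``thermostat``, ``coupling``, ``adaptive``, ``fixtures``,
        ``analysis``.
    """
    if stream not in STREAMS:
        raise KeyError(f"unknown RNG stream {stream!r}; known: {sorted(STREAMS)}")
    if master_seed < 0:
        raise ValueError("master seed must be non-negative")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(STREAMS[stream],))
    return np.random.Generator(np.random.PCG64(ss))


def all_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """All named child generators for one master seed."""
    return {name: child_rng(master_seed, name) for name in STREAMS}
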
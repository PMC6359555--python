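"""Bundled reference inputs.

The dialanine Phi-transition time tables (published mean transition
times from 1 microsecond equilibrium MD and from 50 ns biased runs of
the dipeptide in explicit water, at 300-450 K) are shipped as inputs for
the Arrhenius analysis: fitting ln(1/tau) against 1/T on these tables
reproduces the published activation energies (about 21.05, 18.8 and
9.2 kJ/mol).
"""

from __future__ import annotations

import numpy as np

DIALANINE_TEMPERATURES_K = np.array([300.0, 350.0, 400.0, 450.0])

#: mean Phi transition times (ps) per sampling protocol
DIALANINE_TRANSITION_TIMES_PS = {
    "md": np.array([42696.0, 15759.0, 5877.0, 2550.0]),
    "path_sampling": np.array([7228.0, 614.0, 634.0, 522.0]),
    "principal_components": np.array([3873.0, 1325.0, 1236.0, 1083.0]),
}


def dialanine_table(protocol: str):
    """(temperatures K, transition times ps) for one sampling protocol.

    Protocols: ``md`` (equilibrium), ``path_sampling`` (multi-path bias),
    ``principal_components`` (bias along slowest principal components).
    """
    if protocol not in DIALANINE_TRANSITION_TIMES_PS:
        raise KeyError(
            f"unknown protocol {protocol!r}; "
            f"known: {sorted(DIALANINE_TRANSITION_TIMES_PS)}"
        )
    return DIALANINE_TEMPERATURES_K.copy(), DIALANINE_TRANSITION_TIMES_PS[protocol].copy()


def write_arrhenius_tables(directory) -> list[str]:
    """Write the three bundled (T, tau) tables as two-column TSV files."""
    import os

    paths = []
    for name, tau in DIALANINE_TRANSITION_TIMES_PS.items():
        path = os.path.join(directory, f"dialanine_{name}.tsv")
        with open(path, "w") as fh:
            fh.write("# T_K\ttau_ps\n")
            for T, t in zip(DIALANINE_TEMPERATURES_K, tau):
                fh.write(f"{T:g}\t{t:g}\n")
        paths.append(path)
    return paths


def read_t_tau_table(path):
    """Read a plain two-column (T, tau) table (whitespace separated,
    ``#`` comments)."""
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if data.shape[1] != 2:
        raise ValueError("expected a two-column T/tau table")
    return data[:, 0], data[:, 1]
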
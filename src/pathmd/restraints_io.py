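"""Distance-restraint tables, distances and fulfillment statistics.

The restraint dialect is a tab-separated table with ``#`` comments and
columns ``id  group1  group2  d0_nm  kind``: groups are comma-separated
0-based atom indices (group 2 holds a single atom by default), ``d0`` is
the target distance in nm and ``kind`` is ``noe`` (NMR NOESY-derived) or
``xlink`` (chemical crosslink).  Group semantics follow the crosslink
convention — all atoms of the first residue against one atom of the
second — and the effective distance of a record is the minimum over
group-1 atoms of the distance to the group-2 atom.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

KINDS = ("noe", "xlink")


@dataclass
class RestraintRecord:
    id: int
    group1: list[int]
    group2: list[int]
    d0: float
    kind: str = "xlink"

    def __post_init__(self):
        self.group1 = [int(i) for i in self.group1]
        self.group2 = [int(i) for i in self.group2]
        if not self.group1 or not self.group2:
            raise ValueError(f"restraint {self.id}: empty atom group")
        if set(self.group1) & set(self.group2):
            raise ValueError(f"restraint {self.id}: groups must be disjoint")
        if min(self.group1 + self.group2) < 0:
            raise ValueError(f"restraint {self.id}: negative atom index")
        if self.d0 <= 0:
            raise ValueError(f"restraint {self.id}: d0 must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"restraint {self.id}: unknown kind {self.kind!r}")


class RestraintParseError(ValueError):
    """Malformed restraint table; the message names the offending line."""


def _parse_group(text: str, line_no: int) -> list[int]:
    try:
        return [int(tok) for tok in text.split(",") if tok != ""]
    except ValueError:
        raise RestraintParseError(f"line {line_no}: malformed atom indices {text!r}")


def parse_restraint_table(path) -> list[RestraintRecord]:
    """Read a restraint TSV; raises :class:`RestraintParseError` with the
    line number on any malformed record, and rejects duplicate ids."""
    records: list[RestraintRecord] = []
    seen: set[int] = set()
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip() or row[0].lstrip().startswith("#"):
                continue
            if len(row) != 5:
                raise RestraintParseError(
                    f"line {line_no}: expected 5 tab-separated fields, got {len(row)}"
                )
            try:
                rid = int(row[0])
            except ValueError:
                raise RestraintParseError(f"line {line_no}: bad id {row[0]!r}")
            if rid in seen:
                raise RestraintParseError(f"line {line_no}: duplicate id {rid}")
            seen.add(rid)
            g1 = _parse_group(row[1], line_no)
            g2 = _parse_group(row[2], line_no)
            try:
                d0 = float(row[3])
            except ValueError:
                raise RestraintParseError(f"line {line_no}: bad d0 {row[3]!r}")
            try:
                records.append(RestraintRecord(rid, g1, g2, d0, row[4].strip()))
            except ValueError as err:
                raise RestraintParseError(f"line {line_no}: {err}")
    return records


def write_restraint_table(records, path) -> None:
    """Write records in the same TSV dialect (round-trips exactly)."""
    with open(path, "w", newline="") as fh:
        fh.write("# id\tgroup1\tgroup2\td0_nm\tkind\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in records:
            w.writerow(
                [r.id, ",".join(map(str, r.group1)), ",".join(map(str, r.group2)),
                 repr(float(r.d0)), r.kind]
            )


def effective_distance(q, record: RestraintRecord):
    """Minimum-distance geometry of a restraint on coordinates ``q``.

    Returns ``(d12, q12, (atom1, atom2))`` with d12 the minimum over
    group-1 atoms of the distance to the (single) group-2 atom, q12 the
    vector q_atom1 - q_atom2 of the realizing pair, atom order group 1
    minus group 2.  Coincident atoms give d12 = 0 (caller skips).
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    idx = record.group1 + record.group2
    if max(idx) >= n:
        raise IndexError(
            f"restraint {record.id} references atom {max(idx)} "
            f"but the system has {n} atoms"
        )
    a2 = record.group2[0]
    g1 = record.group1
    vecs = q[g1] - q[a2]
    dists = np.sqrt((vecs * vecs).sum(axis=1))
    j = int(np.argmin(dists))
    return float(dists[j]), vecs[j].copy(), (int(g1[j]), int(a2))


@dataclass
class FulfillmentReport:
    """Per-restraint difference series Delta(t) = d(t) - d0 and summaries."""

    times: np.ndarray
    restraint_ids: list[int]
    delta: np.ndarray  # (frames, n_restraints)
    d0: np.ndarray

    summary: dict = field(init=False)

    def __post_init__(self):
        self.summary = {}
        for j, rid in enumerate(self.restraint_ids):
            series = self.delta[:, j]
            self.summary[rid] = {
                "min": float(series.min()),
                "mean": float(series.mean()),
                "fulfilled_fraction": float(np.mean(series <= 0.0)),
            }

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("restraint_id,t,delta_nm\n")
            for j, rid in enumerate(self.restraint_ids):
                for t, v in zip(self.times, self.delta[:, j]):
                    fh.write(f"{rid},{t:.6f},{v:.9g}\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.summary.items()}, fh, indent=1)

    def delta_landscape(self, restraint_id: int, temperature: float,
                        bins: int = 50, ref: str = "max"):
        """Free-energy profile of Delta for one restraint (kBT units)."""
        from pathmd.kinetics_analysis import free_energy_landscape

        j = self.restraint_ids.index(restraint_id)
        return free_energy_landscape(self.delta[:, j], bins, temperature, ref=ref)


def fulfillment_report(trajectory, records) -> FulfillmentReport:
    """Compute Delta(t) = d(t) - d0 per restraint over a trajectory.

    ``trajectory`` is a :class:`~pathmd.engine.TrajectoryRecord` (or any
    object with ``times`` and ``positions``).
    """
    times = np.asarray(trajectory.times)
    pos = np.asarray(trajectory.positions)
    delta = np.empty((len(times), len(records)))
    for fi in range(len(times)):
        for j, rec in enumerate(records):
            d12, _, _ = effective_distance(pos[fi], rec)
            delta[fi, j] = d12 - rec.d0
    return FulfillmentReport(
        times=times,
        restraint_ids=[r.id for r in records],
        delta=delta,
        d0=np.asarray([r.d0 for r in records]),
    )
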
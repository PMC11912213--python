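"""Domain types and plain-text I/O for kinetic transition networks.

A kinetic transition network (KTN) is a graph whose nodes are local minima of
a potential energy surface and whose edges are the transition states (index-1
saddle points) connecting them.  The file dialect follows the de-facto
PATHSAMPLE layout: whitespace-separated records, one stationary point per
line, energy first.  Minima and transition states are numbered 1..N in file
order, because landscape databases conventionally label structures by the
order in which they were discovered.

Units are kcal/mol throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class KTNParseError(ValueError):
    """Raised when a min.data / ts.data record cannot be parsed."""


class KTNValidationError(ValueError):
    """Raised by strict validation when the network is inconsistent."""


@dataclass(frozen=True)
class Minimum:
    """A local minimum of the landscape.

    Parameters
    ----------
    id : int
        1-based database index (order of discovery / file order).
    energy : float
        Potential energy in kcal/mol.
    log_freq_product : float
        Log of the normal-mode frequency product.  Unused under the
        uniform-frequency approximation; kept for database round-trips.
    degeneracy : int
        Point-group order; defaults to 1.
    """

    id: int
    energy: float
    log_freq_product: float = 0.0
    degeneracy: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"minimum {self.id}: energy must be finite")
        if self.degeneracy < 1:
            raise ValueError(f"minimum {self.id}: degeneracy must be >= 1")


@dataclass(frozen=True)
class TransitionState:
    """An index-1 saddle connecting two minima (by database id)."""

    id: int
    energy: float
    min1: int
    min2: int
    log_freq_product: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"transition state {self.id}: energy must be finite")
        if self.min1 <= 0 or self.min2 <= 0:
            raise KTNParseError(
                f"transition state {self.id}: minimum ids must be positive "
                f"(got {self.min1}, {self.min2})"
            )

    @property
    def is_degenerate(self) -> bool:
        """A degenerate rearrangement connects a minimum to itself."""
        return self.min1 == self.min2


@dataclass
class KTN:
    """A validated kinetic transition network.

    ``adjacency`` maps each minimum id to the list of incident transition
    states (parallel transition states between the same pair are kept as
    separate records, contributing additively to rates).
    """

    minima: dict[int, Minimum]
    transition_states: list[TransitionState]
    adjacency: dict[int, list[TransitionState]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.adjacency:
            self.adjacency = {mid: [] for mid in self.minima}
            for ts in self.transition_states:
                self.adjacency[ts.min1].append(ts)
                if ts.min2 != ts.min1:
                    self.adjacency[ts.min2].append(ts)

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    @property
    def n_ts(self) -> int:
        return len(self.transition_states)

    def energy(self, min_id: int) -> float:
        return self.minima[min_id].energy

    def to_json(self) -> str:
        obj = {
            "minima": [
                {
                    "id": m.id,
                    "energy": m.energy,
                    "log_freq_product": m.log_freq_product,
                    "degeneracy": m.degeneracy,
                }
                for m in sorted(self.minima.values(), key=lambda m: m.id)
            ],
            "ts": [
                {"id": t.id, "energy": t.energy, "min1": t.min1, "min2": t.min2}
                for t in self.transition_states
            ],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "KTN":
        obj = json.loads(text)
        minima = [
            Minimum(
                id=d["id"],
                energy=d["energy"],
                log_freq_product=d.get("log_freq_product", 0.0),
                degeneracy=d.get("degeneracy", 1),
            )
            for d in obj["minima"]
        ]
        ts = [
            TransitionState(
                id=d["id"], energy=d["energy"], min1=d["min1"], min2=d["min2"]
            )
            for d in obj["ts"]
        ]
        return validate_ktn(minima, ts)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_float(token: str, path: str, lineno: int) -> float:
    # landscape databases exported from LaTeX-adjacent tooling sometimes carry
    # a unicode minus sign
    token = token.replace("−", "-")
    try:
        return float(token)
    except ValueError:
        raise KTNParseError(
            f"{path}:{lineno}: malformed numeric field {token!r}"
        ) from None


def read_min_data(path: str | Path) -> list[Minimum]:
    """Read a min.data-style file: one minimum per line, energy first.

    Optional trailing fields are ``log_freq_product`` and ``degeneracy``
    (PATHSAMPLE also stores point-group order and inertia components; any
    extra fields are ignored).
    """
    path = Path(path)
    minima: list[Minimum] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            energy = _parse_float(fields[0], str(path), lineno)
            logfp = _parse_float(fields[1], str(path), lineno) if len(fields) > 1 else 0.0
            degeneracy = 1
            if len(fields) > 2:
                try:
                    degeneracy = max(1, int(float(fields[2])))
                except ValueError:
                    raise KTNParseError(
                        f"{path}:{lineno}: malformed degeneracy field {fields[2]!r}"
                    ) from None
            minima.append(
                Minimum(
                    id=len(minima) + 1,
                    energy=energy,
                    log_freq_product=logfp,
                    degeneracy=degeneracy,
                )
            )
    if not minima:
        raise KTNParseError(f"{path}: empty min.data file")
    return minima


def read_ts_data(path: str | Path) -> list[TransitionState]:
    """Read a ts.data-style file.

    Each line: energy, one metadata field (log frequency product), then the
    two connected minimum ids; extra trailing fields ignored.  An empty file
    is valid and yields an empty list (a network with no kinetics).
    """
    path = Path(path)
    records: list[TransitionState] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise KTNParseError(
                    f"{path}:{lineno}: expected >=4 fields "
                    "(energy, metadata, min1, min2)"
                )
            energy = _parse_float(fields[0], str(path), lineno)
            logfp = _parse_float(fields[1], str(path), lineno)
            try:
                min1, min2 = int(fields[2]), int(fields[3])
            except ValueError:
                raise KTNParseError(
                    f"{path}:{lineno}: malformed minimum index"
                ) from None
            if min1 <= 0 or min2 <= 0:
                raise KTNParseError(
                    f"{path}:{lineno}: minimum ids must be positive"
                )
            records.append(
                TransitionState(
                    id=len(records) + 1,
                    energy=energy,
                    min1=min1,
                    min2=min2,
                    log_freq_product=logfp,
                )
            )
    return records


def write_min_data(minima: Iterable[Minimum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(minima, key=lambda m: m.id):
            fh.write(f"{m.energy:.10f} {m.log_freq_product:.10f} {m.degeneracy}\n")


def write_ts_data(ts: Iterable[TransitionState], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in ts:
            fh.write(
                f"{t.energy:.10f} {t.log_freq_product:.10f} {t.min1} {t.min2}\n"
            )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_ktn(
    minima: Sequence[Minimum],
    transition_states: Sequence[TransitionState],
    policy: str = "clamp",
) -> KTN:
    """Assemble a consistent KTN from parsed tables.

    Drops transition states whose endpoints are missing from the minima table
    or identical (degenerate rearrangements carry no inter-minimum kinetics).
    A transition state lying below one of its endpoints is physically
    inconsistent: under ``policy="clamp"`` its energy is lifted to the higher
    endpoint energy (a zero barrier on that side), under ``policy="strict"``
    a :class:`KTNValidationError` is raised listing the offending ids.
    """
    if policy not in ("clamp", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    min_table = {m.id: m for m in minima}
    if len(min_table) != len(minima):
        raise KTNValidationError("duplicate minimum ids")

    kept: list[TransitionState] = []
    offending: list[int] = []
    for ts in transition_states:
        if ts.is_degenerate:
            logger.warning("dropping degenerate-rearrangement TS %d", ts.id)
            continue
        if ts.min1 not in min_table or ts.min2 not in min_table:
            logger.warning(
                "dropping TS %d: endpoint(s) %d/%d missing from minima table",
                ts.id, ts.min1, ts.min2,
            )
            continue
        floor = max(min_table[ts.min1].energy, min_table[ts.min2].energy)
        if ts.energy < floor:
            if policy == "strict":
                offending.append(ts.id)
                continue
            logger.warning(
                "TS %d energy %.6g below endpoint max %.6g: clamped",
                ts.id, ts.energy, floor,
            )
            ts = TransitionState(
                id=ts.id, energy=floor, min1=ts.min1, min2=ts.min2,
                log_freq_product=ts.log_freq_product,
            )
        kept.append(ts)
    if offending:
        raise KTNValidationError(
            f"transition states below their endpoint minima: {offending}"
        )
    return KTN(minima=dict(min_table), transition_states=kept)


def connected_components(ktn: KTN) -> list[list[int]]:
    """Partition minimum ids by transition-state connectivity.

    Components are ordered largest first; ties and members within a component
    are ordered by minimum id, so the result is invariant under permutation
    of the transition-state records.
    """
    parent = {mid: mid for mid in ktn.minima}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ts in ktn.transition_states:
        ra, rb = find(ts.min1), find(ts.min2)
        if ra != rb:
            parent[ra] = rb

    groups: dict[int, list[int]] = {}
    for mid in ktn.minima:
        groups.setdefault(find(mid), []).append(mid)
    comps = [sorted(g) for g in groups.values()]
    comps.sort(key=lambda g: (-len(g), g[0]))
    return comps
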
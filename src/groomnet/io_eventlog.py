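"""Contact-event logs, edge lists and ego summaries.

The atomic observation is a *contact event*: on some day, an actor directed
one act of social grooming (a message, a call, a bout of fur cleaning) at a
partner.  Tie strength ``d_ij`` is the number of *distinct days* on which
actor ``i`` groomed partner ``j``; repeated same-day acts collapse to one
unit of strength.  An :class:`EgoSummary` collects, per actor, the strength
map ``d``, the number of partners ``N``, the mean strength ``m`` and the
number of active days ``u`` — the unit of observation for the trade-off
regression.

Grooming is treated as directed (giver -> receiver); nothing here
symmetrises.  Day indices are 1-based integers inside an observation window
``[1, T]``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEvent",
    "EgoSummary",
    "read_event_log",
    "aggregate_egos",
    "write_edge_list",
    "read_edge_list",
    "write_ego_table",
    "read_ego_table",
]


@dataclass(frozen=True)
class ContactEvent:
    """One directed grooming act: ``actor`` groomed ``partner`` on ``day``."""

    actor: str
    partner: str
    day: int

    def __post_init__(self) -> None:
        if self.actor == self.partner:
            raise ValueError(f"self-grooming event: {self.actor!r} on day {self.day}")
        if not isinstance(self.day, int) or self.day < 1:
            raise ValueError(f"day must be a positive integer, got {self.day!r}")


@dataclass
class EgoSummary:
    """Per-ego relationship summary.

    Parameters
    ----------
    ego : str
        Ego identifier.
    N : float
        Number of social relationships (alters).  Integer for observed data;
        real-valued summaries are allowed for noise-free synthetic egos.
    m : float
        Mean tie strength, ``sum(d)/N``.
    u : float
        Number of distinct days with at least one outgoing event.
    C : float or None
        Total grooming cost ``u**b``; filled in once the cost exponent ``b``
        is known (see :func:`groomnet.tradeoff_regression.compute_C`).
    d : mapping alter -> strength, optional
        The full strength map.  When present it must be consistent with
        ``N`` and ``m``.
    """

    ego: str
    N: float
    m: float
    u: float
    C: float | None = None
    d: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.d is not None:
            if len(self.d) != self.N:
                raise ValueError(f"ego {self.ego!r}: N={self.N} != len(d)={len(self.d)}")
            mean_d = sum(self.d.values()) / len(self.d)
            if not math.isclose(mean_d, self.m, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(f"ego {self.ego!r}: m={self.m} != mean(d)={mean_d}")
            dmax = max(self.d.values())
            if dmax > self.u + 1e-9:
                raise ValueError(f"ego {self.ego!r}: max(d)={dmax} exceeds u={self.u}")

    @classmethod
    def from_strengths(
        cls, ego: str, d: Mapping[str, float], u: float, C: float | None = None
    ) -> "EgoSummary":
        d = dict(d)
        if not d:
            raise ValueError(f"ego {ego!r}: empty strength map")
        return cls(ego=ego, N=len(d), m=sum(d.values()) / len(d), u=u, C=C, d=d)


def _sniff_separator(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_event_log(
    path: str | Path,
    sep: str | None = None,
    header: str | bool = "auto",
) -> list[ContactEvent]:
    """Read a contact-event log (columns: actor, partner, day).

    ``sep=None`` sniffs tab-vs-comma from the first line.  ``header`` may be
    True, False or ``"auto"`` (skip the first row when its third column does
    not parse as an integer).  Malformed rows — wrong column count,
    non-integer day, actor equal to partner — are skipped with a warning
    that includes the 1-based line number; they never abort the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    events: list[ContactEvent] = []
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            logger.warning("event log %s is empty", path)
            return events
        if sep is None:
            sep = _sniff_separator(first)
        rows = [(1, next(iter(csv.reader([first], delimiter=sep))))]
        rows += list(enumerate(csv.reader(fh, delimiter=sep), start=2))
    start = 0
    if header is True:
        start = 1
    elif header == "auto":
        cols = rows[0][1]
        if len(cols) >= 3:
            try:
                int(cols[2])
            except ValueError:
                start = 1
    n_bad = 0
    for lineno, cols in rows[start:]:
        if not cols or (len(cols) == 1 and not cols[0].strip()):
            continue
        if len(cols) < 3:
            logger.warning("line %d: expected 3 columns, got %d", lineno, len(cols))
            n_bad += 1
            continue
        actor, partner = cols[0].strip(), cols[1].strip()
        try:
            day = int(cols[2])
        except ValueError:
            logger.warning("line %d: non-integer day %r", lineno, cols[2])
            n_bad += 1
            continue
        if actor == partner:
            logger.warning("line %d: actor equals partner (%r); row rejected", lineno, actor)
            n_bad += 1
            continue
        if day < 1:
            logger.warning("line %d: non-positive day %d", lineno, day)
            n_bad += 1
            continue
        events.append(ContactEvent(actor, partner, day))
    if n_bad:
        logger.warning("event log %s: %d malformed row(s) skipped", path, n_bad)
    return events


def aggregate_egos(events: Iterable[ContactEvent], T: int) -> list[EgoSummary]:
    """Aggregate events into per-ego summaries over the window ``[1, T]``.

    ``d_ij`` counts distinct days with at least one i->j event; ``u_i``
    counts the ego's distinct active days.  Aggregation is invariant to
    event order.  Raises if any event day exceeds ``T``.
    """
    days_by_dyad: dict[str, dict[str, set[int]]] = {}
    active_days: dict[str, set[int]] = {}
    for ev in events:
        if ev.day > T:
            raise ValueError(f"event day {ev.day} outside observation window [1, {T}]")
        days_by_dyad.setdefault(ev.actor, {}).setdefault(ev.partner, set()).add(ev.day)
        active_days.setdefault(ev.actor, set()).add(ev.day)
    summaries = []
    for ego in sorted(days_by_dyad):
        d = {alter: float(len(days)) for alter, days in days_by_dyad[ego].items()}
        summaries.append(EgoSummary.from_strengths(ego, d, u=float(len(active_days[ego]))))
    return summaries


def write_edge_list(edges: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    """Write a directed tie-strength edge list as TSV (ego, alter, strength).

    Strengths are serialised with ``repr`` so the file round-trips floats
    bit-exactly.  An empty network yields a header-only file.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ego\talter\tstrength\n")
        for ego in edges:
            for alter, s in edges[ego].items():
                if s < 0:
                    raise ValueError(f"negative strength {s} for ({ego}, {alter})")
                fh.write(f"{ego}\t{alter}\t{s!r}\n")


def read_edge_list(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a TSV edge list written by :func:`write_edge_list`."""
    path = Path(path)
    edges: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and not header.startswith("ego\talter"):
            raise ValueError(f"{path}: unrecognised edge-list header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            edges.setdefault(parts[0], {})[parts[1]] = float(parts[2])
    return edges


def write_ego_table(egos: Sequence[EgoSummary], path: str | Path) -> None:
    """Write ego summaries as CSV with columns ego, N, m, u, C."""
    with open(path, "w") as fh:
        fh.write("ego,N,m,u,C\n")
        for e in egos:
            c = "" if e.C is None else repr(e.C)
            fh.write(f"{e.ego},{e.N!r},{e.m!r},{e.u!r},{c}\n")


def read_ego_table(path: str | Path) -> list[EgoSummary]:
    """Read an ego-summary CSV written by :func:`write_ego_table`."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            C = float(row["C"]) if row.get("C") else None
            out.append(
                EgoSummary(
                    ego=row["ego"],
                    N=float(row["N"]),
                    m=float(row["m"]),
                    u=float(row["u"]),
                    C=C,
                )
            )
    return out
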
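"""Daily co-occurrence and the simple-ratio association index.

Association networks are built at a resolution of one day: a pair of
individuals is "together" on a day if they co-occur in at least one
retained affiliative interaction event that day, and the dyadic tie
weight is the simple ratio index — the number of days the pair was seen
together divided by the number of days on which either member was seen.
Tree-foraging records (proximity forced by the substrate) and agonistic
records are excluded before counting, as are whole events involving any
unmarked individual.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import InteractionType, NetworkPeriod, ObservationRecord
from .errors import ConsistencyError, DomainError

__all__ = [
    "AFFILIATIVE_TYPES",
    "DailyPresence",
    "DailyCooccurrence",
    "AssociationMatrix",
    "filter_records",
    "build_presence",
    "build_cooccurrence",
    "simple_ratio_index",
    "build_association_matrix",
    "association_matrix_from_records",
]

AFFILIATIVE_TYPES = frozenset(
    {InteractionType.AFFILIATIVE_CONTACT, InteractionType.COORDINATED_ACTIVITY}
)


def filter_records(
    records: Sequence[ObservationRecord],
    keep_unmarked: bool = False,
) -> list[ObservationRecord]:
    """Apply the network-analysis exclusion filters.

    Retains only affiliative-contact and coordinated-activity records
    (agonistic and tree-foraging interactions do not express positive
    association) and, unless ``keep_unmarked``, drops every record of any
    event in which an unmarked individual took part, since such events
    cannot be attributed to identified dyads.
    """
    if keep_unmarked:
        tainted: set[str] = set()
    else:
        tainted = {r.event_id for r in records if not r.marked}
    return [
        r
        for r in records
        if r.interaction_type in AFFILIATIVE_TYPES and r.event_id not in tainted
    ]


@dataclass
class DailyPresence:
    """Boolean individual-by-day matrix of retained sightings."""

    ids: list[str]
    days: list[_dt.date]
    matrix: np.ndarray  # shape (n_individuals, n_days), bool
    period: NetworkPeriod | None = None

    def days_seen(self, individual: str) -> set[_dt.date]:
        i = self.ids.index(individual)
        return {d for d, present in zip(self.days, self.matrix[i]) if present}


@dataclass
class DailyCooccurrence:
    """Per-day sets of unordered pairs co-observed in >=1 retained event."""

    pairs_by_day: dict[_dt.date, set[frozenset]]
    period: NetworkPeriod | None = None


def build_presence(
    records: Sequence[ObservationRecord],
    period: NetworkPeriod | None = None,
) -> DailyPresence:
    recs = [r for r in records if period is None or period.contains(r)]
    ids = sorted({r.individual_id for r in recs})
    days = sorted({r.date for r in recs})
    idx = {v: i for i, v in enumerate(ids)}
    didx = {v: i for i, v in enumerate(days)}
    mat = np.zeros((len(ids), len(days)), dtype=bool)
    for r in recs:
        mat[idx[r.individual_id], didx[r.date]] = True
    return DailyPresence(ids=ids, days=days, matrix=mat, period=period)


def build_cooccurrence(
    records: Sequence[ObservationRecord],
    period: NetworkPeriod | None = None,
) -> DailyCooccurrence:
    recs = [r for r in records if period is None or period.contains(r)]
    by_event: dict[tuple[_dt.date, str], set[str]] = {}
    for r in recs:
        by_event.setdefault((r.date, r.event_id), set()).add(r.individual_id)
    pairs: dict[_dt.date, set[frozenset]] = {}
    for (day, _event), members in by_event.items():
        bucket = pairs.setdefault(day, set())
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                bucket.add(frozenset((members[i], members[j])))
    return DailyCooccurrence(pairs_by_day=pairs, period=period)


def simple_ratio_index(
    days_a: set,
    days_b: set,
    days_together: set,
) -> float:
    """|days together| / |days A union days B|.

    The denominator counts days on which either individual was observed;
    an empty union is an error (the index is undefined, not zero), and
    ``days_together`` must be a subset of the days both were seen.
    """
    days_a, days_b, days_together = set(days_a), set(days_b), set(days_together)
    if not days_together <= (days_a & days_b):
        raise ConsistencyError("days_together must be a subset of days_A ∩ days_B")
    union = days_a | days_b
    if not union:
        raise DomainError("association index undefined: neither individual ever seen")
    return len(days_together) / len(union)


@dataclass
class AssociationMatrix:
    """Symmetric matrix of simple-ratio indices for one network period."""

    ids: list[str]
    matrix: np.ndarray  # shape (n, n), float in [0, 1], zero diagonal
    period: NetworkPeriod | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ConsistencyError("matrix shape does not match id list")
        if not np.allclose(m, m.T):
            raise ConsistencyError("association matrix must be symmetric")
        if np.any(m < 0) or np.any(m > 1):
            raise ConsistencyError("association indices must lie in [0, 1]")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    def index(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_graph(self, drop_zero: bool = True) -> nx.Graph:
        """Weighted graph view (zero-weight dyads omitted by default)."""
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                w = self.matrix[i, j]
                if w > 0 or not drop_zero:
                    g.add_edge(self.ids[i], self.ids[j], weight=float(w))
        return g

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)

    def to_edgelist(self, path: str | Path) -> None:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.matrix[i, j] > 0:
                    rows.append((self.ids[i], self.ids[j], self.matrix[i, j]))
        pd.DataFrame(rows, columns=["id_i", "id_j", "weight"]).to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)


def build_association_matrix(
    presence: DailyPresence,
    cooccurrence: DailyCooccurrence,
) -> AssociationMatrix:
    """Assemble the simple-ratio matrix from presence and co-occurrence.

    Individuals seen on zero days are dropped from the period's network
    with a warning.  Raises :class:`ConsistencyError` if a co-occurring
    pair was not present that day.
    """
    seen_days = {ind: presence.days_seen(ind) for ind in presence.ids}
    zero = [ind for ind, d in seen_days.items() if not d]
    if zero:
        warnings.warn(f"dropping individuals seen on zero days: {zero}", stacklevel=2)
    ids = [i for i in presence.ids if seen_days[i]]
    idset = set(ids)

    together: dict[frozenset, set[_dt.date]] = {}
    for day, pairs in cooccurrence.pairs_by_day.items():
        for pair in pairs:
            a, b = tuple(pair)
            if a not in idset or b not in idset:
                raise ConsistencyError(f"pair {tuple(pair)} co-occurs but is not present")
            if day not in seen_days[a] or day not in seen_days[b]:
                raise ConsistencyError(
                    f"pair {tuple(pair)} co-occurs on {day} without being present"
                )
            together.setdefault(pair, set()).add(day)

    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((ids[i], ids[j]))
            mat[i, j] = mat[j, i] = simple_ratio_index(
                seen_days[ids[i]], seen_days[ids[j]], together.get(pair, set())
            )
    return AssociationMatrix(ids=ids, matrix=mat, period=presence.period)


def association_matrix_from_records(
    records: Sequence[ObservationRecord],
    period: NetworkPeriod | None = None,
    keep_unmarked: bool = False,
) -> AssociationMatrix:
    """Filter records and build the period's association matrix in one step."""
    recs = filter_records(records, keep_unmarked=keep_unmarked)
    return build_association_matrix(
        build_presence(recs, period), build_cooccurrence(recs, period)
    )
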
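"""Within-sample permutation test for nonrandom long-term association.

The null model permutes individuals among the interaction clusters
observed on the same day, preserving every cluster's size and every
individual's daily sighting record ("gambit of the group" swaps).  A
Markov chain of checkerboard swaps generates null association matrices;
the observed dispersion of dyadic association indices is compared
against the null distribution.  A high observed SD indicates preferred
long-term companions; networks failing the test are excluded from all
downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .association import filter_records
from .core_data import NetworkPeriod, ObservationRecord
from .errors import ConfigError, DegenerateInputError

__all__ = [
    "SamplingStructure",
    "PermutationResult",
    "checkerboard_swap",
    "permutation_test",
    "gate_networks",
]

logger = logging.getLogger(__name__)

_STATS = ("sd", "cv", "mean")


@dataclass
class SamplingStructure:
    """Per-day partitions of present individuals into interaction clusters.

    Events on the same day that share individuals are merged into one
    cluster, so clusters within a day are disjoint and their union is
    the set of individuals present that day.
    """

    ids: list[str]
    days: list
    clusters: list[list[list[int]]]  # clusters[d] = list of member-index lists

    @classmethod
    def from_records(
        cls,
        records: Sequence[ObservationRecord],
        period: NetworkPeriod | None = None,
        prefilter: bool = True,
    ) -> "SamplingStructure":
        recs = [r for r in records if period is None or period.contains(r)]
        if prefilter:
            recs = filter_records(recs)
        ids = sorted({r.individual_id for r in recs})
        idx = {v: i for i, v in enumerate(ids)}
        days = sorted({r.date for r in recs})
        clusters: list[list[list[int]]] = []
        for day in days:
            day_events: dict[str, set[int]] = {}
            for r in recs:
                if r.date == day:
                    day_events.setdefault(r.event_id, set()).add(idx[r.individual_id])
            # merge events sharing individuals (union-find over events)
            merged: list[set[int]] = []
            for members in day_events.values():
                hits = [c for c in merged if c & members]
                for c in hits:
                    merged.remove(c)
                    members = members | c
                merged.append(set(members))
            clusters.append([sorted(c) for c in merged])
        return cls(ids=ids, days=days, clusters=clusters)

    def copy(self) -> "SamplingStructure":
        return SamplingStructure(
            ids=list(self.ids),
            days=list(self.days),
            clusters=[[list(c) for c in day] for day in self.clusters],
        )

    def incidence_marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-individual membership counts, flat per-cluster sizes) — swap invariants."""
        counts = np.zeros(len(self.ids), dtype=int)
        sizes = []
        for day in self.clusters:
            for c in day:
                sizes.append(len(c))
                for m in c:
                    counts[m] += 1
        return counts, np.asarray(sizes)

    def presence_days(self) -> list[set[int]]:
        """Day indices on which each individual is present (invariant under swaps)."""
        out: list[set[int]] = [set() for _ in self.ids]
        for d, day in enumerate(self.clusters):
            for c in day:
                for m in c:
                    out[m].add(d)
        return out

    def together_counts(self) -> np.ndarray:
        """Symmetric matrix of days-seen-together counts."""
        n = len(self.ids)
        t = np.zeros((n, n), dtype=np.int32)
        for day in self.clusters:
            for c in day:
                arr = np.asarray(c)
                t[np.ix_(arr, arr)] += 1
        np.fill_diagonal(t, 0)
        return t


def checkerboard_swap(
    structure: SamplingStructure,
    rng: np.random.Generator,
    max_tries: int = 50,
    inplace: bool = False,
    _counts: np.ndarray | None = None,
) -> tuple[SamplingStructure, bool]:
    """Exchange two individuals between two clusters of the same day.

    Preserves every cluster's size and every individual's number of
    cluster memberships.  Returns ``(structure, swapped)``; if no day
    with at least two clusters is found within ``max_tries`` draws the
    input is returned unchanged with ``swapped=False``.

    When ``_counts`` (the days-together count matrix) is supplied it is
    updated in place, allowing the permutation chain to avoid full
    recounts.
    """
    out = structure if inplace else structure.copy()
    eligible_exists = any(len(day) >= 2 for day in out.clusters)
    if not eligible_exists:
        return out, False
    n_days = len(out.clusters)
    for _ in range(max_tries):
        d = int(rng.integers(n_days))
        day = out.clusters[d]
        if len(day) < 2:
            continue
        ci, cj = rng.choice(len(day), size=2, replace=False)
        a_pos = int(rng.integers(len(day[ci])))
        b_pos = int(rng.integers(len(day[cj])))
        a, b = day[ci][a_pos], day[cj][b_pos]
        if _counts is not None:
            x = np.asarray(day[ci])
            y = np.asarray(day[cj])
            x = x[x != a]
            y = y[y != b]
            _counts[a, x] -= 1
            _counts[x, a] -= 1
            _counts[b, x] += 1
            _counts[x, b] += 1
            _counts[b, y] -= 1
            _counts[y, b] -= 1
            _counts[a, y] += 1
            _counts[y, a] += 1
        day[ci][a_pos], day[cj][b_pos] = b, a
        return out, True
    return out, False


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: list[float]
    p_value: float
    n_permutations: int
    stat_name: str
    stabilized: bool
    tail: str = "upper"


def _dyadic_stat(
    counts: np.ndarray,
    denom: np.ndarray,
    stat: str,
    include_zeros: bool = True,
) -> float:
    iu = np.triu_indices(counts.shape[0], k=1)
    d = denom[iu]
    valid = d > 0
    idxs = counts[iu][valid] / d[valid]
    if not include_zeros:
        idxs = idxs[idxs > 0]
    if idxs.size == 0:
        return 0.0
    if stat == "sd":
        return float(np.std(idxs))
    if stat == "cv":
        m = float(np.mean(idxs))
        return float(np.std(idxs) / m) if m > 0 else 0.0
    if stat == "mean":
        return float(np.mean(idxs))
    raise ConfigError(f"unknown statistic {stat!r}; choose from {_STATS}")


def permutation_test(
    structure: SamplingStructure,
    stat: str = "sd",
    max_perm: int = 10_000,
    burn_in: int = 1_000,
    swaps_per_sample: int = 100,
    stabilization_tol: float = 0.01,
    tail: str = "upper",
    include_zeros: bool = True,
    block: int = 1_000,
    rng: np.random.Generator | int | None = None,
) -> PermutationResult:
    """Markov-chain permutation test for preferred/avoided companions.

    A chain of checkerboard swaps is run (``burn_in`` swaps, then
    ``swaps_per_sample`` swaps between retained permutations).  For each
    retained permutation the association matrix is recomputed (the
    denominator — days each individual was seen — is invariant, so only
    days-together counts are updated) and the chosen statistic of the
    dyadic indices recorded.  The upper tail (observed SD larger than
    null) indicates long-term preferred companions; ``tail="lower"``
    tests for avoidance.  The p-value uses the add-one rule
    ``(count + 1) / (n + 1)`` and permutations stop early once the
    p-value changes by less than ``stabilization_tol`` between
    consecutive ``block``-permutation blocks.
    """
    if stat not in _STATS:
        raise ConfigError(f"unknown statistic {stat!r}; choose from {_STATS}")
    if max_perm < 100:
        raise ConfigError("max_perm must be at least 100")
    if tail not in ("upper", "lower"):
        raise ConfigError("tail must be 'upper' or 'lower'")
    if len(structure.ids) < 2 or len(structure.days) < 2:
        raise DegenerateInputError("need >=2 individuals and >=2 days for the test")

    rng = np.random.default_rng(rng)
    work = structure.copy()

    presence = work.presence_days()
    n = len(work.ids)
    n_days_seen = np.array([len(s) for s in presence])
    denom = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            denom[i, j] = denom[j, i] = len(presence[i] | presence[j])

    counts = work.together_counts().astype(np.int64)
    observed = _dyadic_stat(counts, denom, stat, include_zeros)

    for _ in range(burn_in):
        checkerboard_swap(work, rng, inplace=True, _counts=counts)

    null_stats: list[float] = []
    exceed = 0  # null >= observed (upper) or <= observed (lower)
    stabilized = False
    prev_p = None
    done = 0
    while done < max_perm:
        todo = min(block, max_perm - done)
        for _ in range(todo):
            for _ in range(swaps_per_sample):
                checkerboard_swap(work, rng, inplace=True, _counts=counts)
            s = _dyadic_stat(counts, denom, stat, include_zeros)
            null_stats.append(s)
            if (tail == "upper" and s >= observed) or (tail == "lower" and s <= observed):
                exceed += 1
        done += todo
        p = (exceed + 1) / (done + 1)
        if prev_p is not None and abs(p - prev_p) < stabilization_tol:
            stabilized = True
            break
        prev_p = p

    p = (exceed + 1) / (done + 1)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null_stats,
        p_value=p,
        n_permutations=done,
        stat_name=stat,
        stabilized=stabilized,
        tail=tail,
    )


def gate_networks(
    results: Mapping[object, PermutationResult],
    alpha: float = 0.05,
) -> list:
    """Keep only periods whose networks show nonrandom association (p < alpha)."""
    retained = []
    for key, res in results.items():
        if res.p_value < alpha:
            retained.append(key)
        else:
            logger.info(
                "network %s excluded: permutation p=%.4f >= alpha=%.3f",
                key, res.p_value, alpha,
            )
    if not retained:
        logger.warning("no networks passed the permutation gate at alpha=%.3f", alpha)
    return retained
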
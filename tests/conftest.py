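"""Shared fixtures: tiny observation sets, random graphs, sampling structures."""

import datetime as dt

import networkx as nx
import numpy as np
import pytest

from socnetlong.core_data import InteractionType, ObservationRecord
from socnetlong.permtest import SamplingStructure

DAY0 = dt.date(2003, 3, 1)


def day(i: int) -> dt.date:
    return DAY0 + dt.timedelta(days=i)


def rec(d, event, ind, itype=InteractionType.AFFILIATIVE_CONTACT, site="A", marked=True):
    return ObservationRecord(
        date=day(d) if isinstance(d, int) else d,
        site=site, event_id=str(event), individual_id=str(ind),
        interaction_type=itype, marked=marked,
    )


@pytest.fixture
def pair_records():
    """Two individuals interacting in one event on one day."""
    return [rec(0, "e1", "a"), rec(0, "e1", "b")]


def random_records(rng, n_ind=6, n_days=10, p_present=0.6, p_pair=0.3):
    """Random daily observation records: present pairs interact i.i.d."""
    ids = [f"i{j}" for j in range(n_ind)]
    records = []
    event = 0
    for d in range(n_days):
        present = [i for i in ids if rng.random() < p_present]
        for a_pos in range(len(present)):
            for b_pos in range(a_pos + 1, len(present)):
                if rng.random() < p_pair:
                    event += 1
                    records.append(rec(d, f"e{event}", present[a_pos]))
                    records.append(rec(d, f"e{event}", present[b_pos]))
    return records


def random_weighted_graph(rng, n=8, p_edge=0.5):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                g.add_edge(i, j, weight=float(rng.uniform(0.05, 1.0)))
    return g


def null_structure(seed, n=12, n_days=15, clusters_per_day=3):
    """Sampling structure with individuals shuffled uniformly into clusters."""
    rng = np.random.default_rng(seed)
    clusters = []
    for _ in range(n_days):
        perm = rng.permutation(n)
        clusters.append(
            [sorted(perm[i::clusters_per_day].tolist()) for i in range(clusters_per_day)]
        )
    return SamplingStructure(
        ids=[f"i{j}" for j in range(n)], days=list(range(n_days)), clusters=clusters
    )


def two_clique_structure(n_days=15, half=6):
    """Two fixed cliques that always co-occur: maximal companionship signal."""
    clusters = [[list(range(half)), list(range(half, 2 * half))] for _ in range(n_days)]
    return SamplingStructure(
        ids=[f"i{j}" for j in range(2 * half)], days=list(range(n_days)),
        clusters=clusters,
    )
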
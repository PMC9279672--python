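"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fosnet.behavior import Event, RatioSchedule, SessionLog, response_ratio
from fosnet.connectivity import CorrelationMatrix, CountTable


def completed_trials_log(
    n_trials: int,
    schedule: RatioSchedule | None = None,
    incorrect_per_trial: int = 0,
    touch_interval: float = 5.0,
) -> SessionLog:
    """A valid log in which the subject completes trials 1..n_trials."""
    schedule = schedule or RatioSchedule.progressive()
    events: list[Event] = []
    t = 0.0
    for m in range(1, n_trials + 1):
        events.append(Event(t, "trial_start"))
        for _ in range(incorrect_per_trial):
            t += touch_interval
            events.append(Event(t, "incorrect_touch"))
        for _ in range(response_ratio(schedule, m)):
            t += touch_interval
            events.append(Event(t, "correct_touch"))
        t += 2.0
        events.append(Event(t, "reward_collected"))
        t += 30.0
    return SessionLog(events=events, schedule=schedule)


def table_from_array(
    data, regions: list[str] | None = None, group: str = "g"
) -> CountTable:
    arr = np.asarray(data)
    regions = regions or [f"R{i}" for i in range(arr.shape[1])]
    values = pd.DataFrame(arr, columns=regions,
                          index=[f"s{i}" for i in range(arr.shape[0])])
    return CountTable(values=values, group=group)


def corr_from_array(m, n: int, regions: list[str] | None = None) -> CorrelationMatrix:
    m = np.asarray(m, dtype=float)
    regions = regions or [f"R{i}" for i in range(m.shape[0])]
    return CorrelationMatrix(r=pd.DataFrame(m, index=regions, columns=regions), n=n)


def _all_simple_paths(adj: dict, s, t) -> list[tuple]:
    """All simple s->t paths by plain depth-first enumeration."""
    out: list[tuple] = []
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            out.append(path)
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + (nxt,)))
    return out


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Exhaustive shortest-path betweenness, independent of networkx's
    Brandes implementation: enumerate every simple path per (s, t) pair by
    depth-first search, keep the shortest, and credit interior nodes with
    sigma_st(v)/sigma_st. Each unordered pair is counted once (the
    undirected convention); disconnected pairs contribute nothing."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(list(g.nodes), 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        shortest_paths = [p for p in paths if len(p) == shortest]
        sigma = len(shortest_paths)
        for path in shortest_paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def random_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.Graph:
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j)
    return g


@pytest.fixture
def progressive_schedule() -> RatioSchedule:
    return RatioSchedule.progressive()
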
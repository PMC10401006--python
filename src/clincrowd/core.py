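"""Shared mechanics of the three-round networked-clinician experiment.

Domain types (topology, trial configuration, per-round responses), the
degree-regular random network constructor, the neighbor-mean peer signal,
2:1 condition allocation, and structural validation of trial records.

Conditions: each trial runs 40 clinicians for three rounds, either embedded
in a fixed egalitarian network (every clinician has exactly ``z`` contacts,
``z = 4`` by default) or working independently (control).  Networked
clinicians see the arithmetic mean of their contacts' latest risk estimates
before revising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    GenerationFailureError,
    InvalidParametersError,
    NoSignalError,
)

NETWORK = "network"
CONTROL = "control"

#: Seed of the single canonical 40-node, degree-4 topology shared by every
#: networked trial (the study reuses one realized topology across trials).
CANONICAL_TOPOLOGY_SEED = 1724


@dataclass(frozen=True)
class NetworkTopology:
    """Simple undirected z-regular graph over trial participants.

    ``edges`` holds unordered node pairs stored as sorted tuples.
    """

    n_nodes: int
    degree: int
    edges: frozenset

    def __post_init__(self):
        if self.n_nodes <= 0 or self.degree <= 0:
            raise InvalidParametersError("n_nodes and degree must be positive")
        for a, b in self.edges:
            if a == b:
                raise InvalidParametersError(f"self-loop at node {a}")
        if len(self.edges) != self.n_nodes * self.degree // 2:
            raise InvalidParametersError(
                f"edge count {len(self.edges)} != n*z/2 = "
                f"{self.n_nodes * self.degree // 2}"
            )

    @cached_property
    def adjacency(self) -> dict:
        adj = {i: [] for i in range(self.n_nodes)}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return {k: tuple(sorted(v)) for k, v in adj.items()}

    def neighbors(self, node: int) -> tuple:
        return self.adjacency[node]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def is_regular(self) -> bool:
        return all(len(v) == self.degree for v in self.adjacency.values())

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_graph())


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one trial: vignette, condition, panel dimensions."""

    vignette_id: str
    condition: str
    truth: float
    options: tuple
    correct_option: str
    n_clinicians: int = 40
    n_rounds: int = 3

    def __post_init__(self):
        if self.condition not in (NETWORK, CONTROL):
            raise InvalidParametersError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.truth <= 100.0:
            raise InvalidParametersError("truth must lie in [0, 100]")
        if self.correct_option not in self.options:
            raise InvalidParametersError("correct_option not among options")
        if self.n_rounds < 2:
            raise InvalidParametersError("need at least two rounds")


@dataclass(frozen=True)
class ClinicianRoundResponse:
    """One clinician's risk estimate (0-100) and recommendation at one round."""

    clinician_id: str
    round: int
    estimate: float
    recommendation: str


@dataclass
class TrialRecord:
    """One trial's configuration, optional topology, and full response panel.

    ``node_of`` maps clinician id to network node id for networked trials.
    """

    trial_id: str
    config: TrialConfig
    responses: list
    topology: Optional[NetworkTopology] = None
    node_of: Optional[dict] = None

    def clinician_ids(self) -> list:
        seen = dict.fromkeys(r.clinician_id for r in self.responses)
        return list(seen)

    def estimates(self, round: int) -> dict:
        return {
            r.clinician_id: r.estimate for r in self.responses if r.round == round
        }

    def recommendations(self, round: int) -> dict:
        return {
            r.clinician_id: r.recommendation
            for r in self.responses
            if r.round == round
        }


@dataclass(frozen=True)
class Violation:
    """A named invariant violation and the offending record."""

    rule: str
    detail: str


def generate_regular_random_network(
    n: int, z: int, seed: int, require_connected: bool = True, max_attempts: int = 100
) -> NetworkTopology:
    """Sample a simple connected z-regular random graph on ``n`` nodes.

    Seeded draws are rejected until the realized graph is connected (an
    isolated component would leave nodes without a peer signal).  Identical
    seeds yield identical edge sets.
    """
    if n <= 0 or z <= 0:
        raise InvalidParametersError("n and z must be positive")
    if z >= n:
        raise InvalidParametersError(f"degree z={z} must be < n={n}")
    if (n * z) % 2 != 0:
        raise InvalidParametersError(f"n*z = {n * z} is odd; no z-regular graph exists")

    attempt_seeds = np.random.SeedSequence(seed).generate_state(max_attempts)
    for s in attempt_seeds:
        g = nx.random_regular_graph(z, n, seed=int(s))
        if not require_connected or nx.is_connected(g):
            edges = frozenset(tuple(sorted(e)) for e in g.edges())
            return NetworkTopology(n_nodes=n, degree=z, edges=edges)
    raise GenerationFailureError(
        f"no connected {z}-regular graph on {n} nodes found in {max_attempts} attempts"
    )


def canonical_topology(n: int = 40, z: int = 4) -> NetworkTopology:
    """The fixed master topology reused across all networked trials."""
    return generate_regular_random_network(n, z, seed=CANONICAL_TOPOLOGY_SEED)


def peer_signal(
    topology: NetworkTopology, estimates: Mapping[int, float], node: int
) -> float:
    """Arithmetic mean of a node's neighbors' estimates (own estimate excluded)."""
    nbrs = topology.neighbors(node)
    if not nbrs:
        raise NoSignalError(f"node {node} has no neighbors")
    return float(np.mean([estimates[v] for v in nbrs]))


def allocate_conditions(
    n_invitations: int, ratio_network: int = 2, ratio_control: int = 1, seed: int = 0
):
    """Randomize ``n_invitations`` ids to conditions in a fixed ratio.

    Returns ``(n_network, n_control, assignment)`` where assignment maps
    0-based ids to condition labels via a seeded permutation.  When the
    ratio does not divide evenly, the remainder goes to the network arm.
    """
    if ratio_network <= 0 or ratio_control <= 0 or n_invitations < 0:
        raise InvalidParametersError("ratios must be positive, invitations >= 0")
    total = ratio_network + ratio_control
    base = n_invitations // total
    remainder = n_invitations - base * total
    n_network = base * ratio_network + remainder
    n_control = base * ratio_control

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_invitations)
    assignment = {
        int(i): (NETWORK if rank < n_network else CONTROL)
        for rank, i in enumerate(order)
    }
    return n_network, n_control, assignment


def validate_trial(trial: TrialRecord) -> list:
    """Check a trial record's structural invariants; return violations.

    An empty list means the record is well-formed.  Violations are returned,
    never raised, so callers can collect them across a whole dataset.
    """
    out = []
    cfg = trial.config
    counts = {}
    for r in trial.responses:
        counts.setdefault(r.clinician_id, []).append(r.round)
        if not 0.0 <= r.estimate <= 100.0:
            out.append(
                Violation(
                    "estimate-range",
                    f"trial {trial.trial_id} clinician {r.clinician_id} "
                    f"round {r.round}: estimate {r.estimate}",
                )
            )
        if r.recommendation not in cfg.options:
            out.append(
                Violation(
                    "unknown-recommendation",
                    f"trial {trial.trial_id} clinician {r.clinician_id} "
                    f"round {r.round}: {r.recommendation!r}",
                )
            )

    expected = list(range(1, cfg.n_rounds + 1))
    if len(counts) != cfg.n_clinicians:
        out.append(
            Violation(
                "panel-size",
                f"trial {trial.trial_id}: {len(counts)} clinicians, "
                f"expected {cfg.n_clinicians}",
            )
        )
    for cid, rounds in counts.items():
        if sorted(rounds) != expected:
            out.append(
                Violation(
                    "panel-completeness",
                    f"trial {trial.trial_id} clinician {cid}: rounds {sorted(rounds)}, "
                    f"expected {expected}",
                )
            )

    if cfg.condition == NETWORK:
        if trial.topology is None:
            out.append(
                Violation(
                    "topology-missing",
                    f"network trial {trial.trial_id} has no topology",
                )
            )
        elif trial.topology.n_nodes != cfg.n_clinicians:
            out.append(
                Violation(
                    "topology-size",
                    f"trial {trial.trial_id}: topology has "
                    f"{trial.topology.n_nodes} nodes, panel has {cfg.n_clinicians}",
                )
            )
    elif trial.topology is not None:
        out.append(
            Violation(
                "topology-in-control",
                f"control trial {trial.trial_id} carries a topology",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Edge-list serialization: header trial_id,node_a,node_b, one edge per row.


def edges_to_frame(trial_id: str, topology: NetworkTopology) -> pd.DataFrame:
    rows = sorted(topology.edges)
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "node_a": [a for a, _ in rows],
            "node_b": [b for _, b in rows],
        }
    )


def write_edge_list(path, trials_or_pairs: Iterable) -> None:
    """Write edge lists for ``(trial_id, topology)`` pairs or TrialRecords."""
    frames = []
    for item in trials_or_pairs:
        if isinstance(item, TrialRecord):
            if item.topology is None:
                continue
            frames.append(edges_to_frame(item.trial_id, item.topology))
        else:
            tid, topo = item
            frames.append(edges_to_frame(tid, topo))
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trial_id", "node_a", "node_b"])
    )
    df.to_csv(path, index=False)


def read_edge_list(path) -> dict:
    """Read an edge-list file back into ``{trial_id: NetworkTopology}``.

    Degree is inferred; files written by :func:`write_edge_list` round-trip
    losslessly for regular topologies.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "node_a", "node_b"}
    if not required.issubset(df.columns):
        raise InvalidParametersError(
            f"edge list missing columns {sorted(required - set(df.columns))}"
        )
    out = {}
    for tid, grp in df.groupby("trial_id", sort=False):
        edges = frozenset(
            tuple(sorted((int(a), int(b))))
            for a, b in zip(grp["node_a"], grp["node_b"])
        )
        nodes = {v for e in edges for v in e}
        n = max(nodes) + 1 if nodes else 0
        deg = 2 * len(edges) // n if n else 0
        out[str(tid)] = NetworkTopology(n_nodes=n, degree=deg, edges=edges)
    return out
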
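"""Seeded synthetic disease-network trios with planted ground truth.

The generator emulates the statistical shape of STRING-derived disease
interactomes: each network is a scale-free graph of ~100 proteins and
~1500–2200 edges grown by preferential attachment.  Across the trio a
configurable subset of protein labels is shared; within the shared labels a
hub-like subset is planted early in the growth order (so it lands in the
top 50% by degree of every network) and a small super-hub subset is planted
as initial-clique members with extra attachment rounds (so it lands in the
top 10% of every network).  The remaining shared labels are attached last
with few edges, keeping them out of every top-50% cut.  An action-map
fixture isolates designated candidates per regulatory layer.

Planted rank guarantees are statistical, not absolute: attachment is random
and a planted label can, rarely, miss its percentile band.  Everything a
downstream test needs to know — planted label lists, per-layer isolation
sets, expected funnel counts — is recorded in a :class:`Manifest`.

All randomness flows from ``numpy.random.default_rng`` seeded with
``(seed, network_index)``, so identical configs produce byte-identical
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .netio import (
    ACTION_MODES,
    ActionEdge,
    Network,
    write_action_table,
    write_edge_list,
)

#: extra uniformly-attached edges per planted super-hub (the "attachment
#: boost" that pushes super-hubs into the global top-10% by degree)
SUPERHUB_BOOST = 42

#: milder boost for planted hub-like labels, keeping them inside the
#: top-50% band without lifting them into the top-10%
HUBLIKE_BOOST = 14

#: boost for per-network "decoy hubs" — disease-unique clique labels that
#: fill the top-10% slots beyond the super-hubs, so boosted shared labels
#: cannot slip into the hub band of every network at once
DECOY_BOOST = 22


_ACTION_STREAM = 104729  # rng stream offset for the action fixture
_SCORE_STREAM = 15485863  # rng stream offset for cosmetic confidence scores


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic cross-disease scenario.

    Defaults reproduce the reference scenario: three cancers of 100
    proteins each connected by ~1484/2164/2012 edges, 42 shared proteins of
    which 36 are hub-like everywhere and 3 are super-hubs everywhere.
    """

    n_per_network: int = 100
    n_networks: int = 3
    target_edges: tuple[int, ...] = (1484, 2164, 2012)
    shared_labels: int = 42
    hublike_shared: int = 36
    superhub_shared: int = 3
    disease_ids: tuple[str, ...] = ("esophageal", "gastric", "intestinal")
    action_isolation_plan: Mapping[str, tuple[str, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.superhub_shared <= self.hublike_shared
                <= self.shared_labels <= self.n_per_network):
            raise ValidationError(
                "need superhub_shared <= hublike_shared <= shared_labels "
                f"<= n_per_network, got {self.superhub_shared}/"
                f"{self.hublike_shared}/{self.shared_labels}/{self.n_per_network}"
            )
        if self.n_networks < 1:
            raise ValidationError("n_networks must be >= 1")
        targets = self.edge_targets()
        max_edges = self.n_per_network * (self.n_per_network - 1) // 2
        for t in targets:
            if not 0 < t <= max_edges:
                raise ValidationError(
                    f"target_edges {t} outside (0, n(n-1)/2 = {max_edges}]"
                )
        if len(self.disease_ids) < self.n_networks:
            raise ValidationError("need one disease_id per network")
        if self.action_isolation_plan is not None:
            bad = set(self.action_isolation_plan) - set(ACTION_MODES)
            if bad:
                raise ValidationError(f"unknown action layers in plan: {bad}")

    def edge_targets(self) -> tuple[int, ...]:
        """Per-network edge targets (an int config value is broadcast)."""
        t = self.target_edges
        if isinstance(t, int):
            return (t,) * self.n_networks
        if len(t) == 1:
            return tuple(t) * self.n_networks
        if len(t) != self.n_networks:
            raise ValidationError(
                f"target_edges has {len(t)} entries for {self.n_networks} networks"
            )
        return tuple(t)

    # ---- planted label bookkeeping -------------------------------------
    def shared_label_list(self) -> list[str]:
        return [f"CMN{i + 1:03d}" for i in range(self.shared_labels)]

    def superhub_labels(self) -> list[str]:
        return self.shared_label_list()[: self.superhub_shared]

    def hublike_labels(self) -> list[str]:
        return self.shared_label_list()[: self.hublike_shared]

    def low_shared_labels(self) -> list[str]:
        return self.shared_label_list()[self.hublike_shared:]

    def unique_labels(self, index: int) -> list[str]:
        disease = self.disease_ids[index]
        n_unique = self.n_per_network - self.shared_labels
        return [f"{disease}_U{i + 1:03d}" for i in range(n_unique)]


@dataclass(frozen=True)
class Manifest:
    """Planted ground truth for a generated scenario.

    Fully determines the expected output of every pipeline stage run on the
    generated files.
    """

    disease_ids: tuple[str, ...]
    n_nodes: tuple[int, ...]
    n_edges: tuple[int, ...]
    shared: tuple[str, ...]
    hublike: tuple[str, ...]
    superhubs: tuple[str, ...]
    isolation_plan: Mapping[str, tuple[str, ...]]
    expected_funnel: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "disease_ids": list(self.disease_ids),
            "n_nodes": list(self.n_nodes),
            "n_edges": list(self.n_edges),
            "shared": list(self.shared),
            "hublike": list(self.hublike),
            "superhubs": list(self.superhubs),
            "isolation_plan": {m: list(v) for m, v in sorted(self.isolation_plan.items())},
            "expected_funnel": dict(self.expected_funnel),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Manifest":
        return cls(
            disease_ids=tuple(d["disease_ids"]),
            n_nodes=tuple(d["n_nodes"]),
            n_edges=tuple(d["n_edges"]),
            shared=tuple(d["shared"]),
            hublike=tuple(d["hublike"]),
            superhubs=tuple(d["superhubs"]),
            isolation_plan={m: tuple(v) for m, v in d["isolation_plan"].items()},
            expected_funnel=dict(d["expected_funnel"]),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True,
                           default_flow_style=False)

    @classmethod
    def read(cls, path: str | Path) -> "Manifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _clique_cap(config: ScenarioConfig) -> int:
    """Largest initial-clique size that cannot crowd planted hub-like labels
    out of the top-50% band (clique members rank above the hub-like block)."""
    slack = 3
    cap = config.superhub_shared + max(
        2, config.n_per_network // 2 - slack - config.hublike_shared
    )
    return min(cap, config.n_per_network)


def _n_decoys(config: ScenarioConfig) -> int:
    """Decoy hubs wanted per network: the top-10% slots not taken by
    super-hubs (zero when nothing is planted)."""
    if config.superhub_shared == 0 and config.hublike_shared == 0:
        return 0
    band = max(1, math.floor(config.n_per_network / 10 + 0.5))
    return max(0, band - config.superhub_shared)


def _solve_m(config: ScenarioConfig, target: int) -> tuple[int, int]:
    """Pick attachment counts (m, m_low) so the edge total lands at or just
    below the target; any shortfall is closed by uniform densification."""
    n = config.n_per_network
    n_low = len(config.low_shared_labels())
    n_super = config.superhub_shared
    n_hublike = config.hublike_shared - n_super
    want_decoys = _n_decoys(config)
    best = None
    for m in range(1, min(_clique_cap(config), n - n_low) + 1):
        m_low = max(1, m // 4)
        n_dec = min(want_decoys, max(m - n_super, 0),
                    n - config.shared_labels)
        total = (m * (m - 1)) // 2 + (n - n_low - m) * m + n_low * m_low \
            + n_super * SUPERHUB_BOOST + n_hublike * HUBLIKE_BOOST \
            + n_dec * DECOY_BOOST
        if best is None or abs(total - target) < abs(best[2] - target):
            best = (m, m_low, total)
    if best is None:
        raise ValidationError("infeasible edge target for this node count")
    return best[0], best[1]


def generate_network(config: ScenarioConfig, index: int) -> Network:
    """Grow one disease network by preferential attachment.

    The initial clique of size ``m`` holds the planted super-hubs and
    disease-unique labels, so the per-network top degree ranks are dominated
    by disease-specific proteins rather than shared ones.  Hub-like labels
    follow immediately after the clique — in a per-network shuffled order,
    which decorrelates their degree ranks across diseases — then the
    shuffled remaining unique labels, and finally the low-ranking shared
    labels with a reduced attachment count.  Extra attachment rounds lift
    planted sets into their percentile bands (``SUPERHUB_BOOST`` extra
    uniformly-chosen edges per super-hub, ``HUBLIKE_BOOST`` per hub-like
    label), and a preferential densification phase tops the edge count up
    to the target.  Deterministic for a given ``(config.seed, index)``.
    """
    if not 0 <= index < config.n_networks:
        raise ValidationError(f"network index {index} out of range")
    rng = np.random.default_rng((config.seed, index))
    target = config.edge_targets()[index]
    m, m_low = _solve_m(config, target)

    superhubs = config.superhub_labels()
    hublike_rest = config.hublike_labels()[len(superhubs):]
    low = config.low_shared_labels()
    unique = config.unique_labels(index)
    rng.shuffle(unique)
    rng.shuffle(hublike_rest)

    k_u = min(max(m - len(superhubs), 0), len(unique))
    seed_nodes = (superhubs + unique[:k_u])[:max(m, 1)]
    growth = hublike_rest + unique[k_u:]
    decoys = unique[:min(_n_decoys(config), k_u)]

    adj: dict[str, set[str]] = {
        v: set() for v in superhubs + hublike_rest + low + unique
    }
    pool: list[str] = []  # one entry per unit of degree

    def add_edge(u: str, v: str) -> None:
        adj[u].add(v)
        adj[v].add(u)
        pool.append(u)
        pool.append(v)

    for i, u in enumerate(seed_nodes):
        for v in seed_nodes[i + 1:]:
            add_edge(u, v)
    if len(seed_nodes) == 1:
        pool.append(seed_nodes[0])

    inserted = len(seed_nodes)

    def attach(v: str, k: int) -> None:
        k = min(k, inserted)
        chosen: set[str] = set()
        snapshot = list(pool)
        while len(chosen) < k:
            chosen.add(snapshot[rng.integers(len(snapshot))])
        # sorted: set iteration order must not leak into the pool sequence,
        # or generation would differ across processes (hash randomisation)
        for u in sorted(chosen):
            add_edge(u, v)

    for v in growth:
        attach(v, m)
        inserted += 1
    for v in low:
        attach(v, m_low)
        inserted += 1

    # uniform densification up to the edge target (minus the boost rounds
    # still to come); the heavy tail is already set by the growth phase, and
    # uniform pair selection preserves the planted degree ordering
    all_labels = sorted(adj)
    n_boost = (len(superhubs) * SUPERHUB_BOOST
               + len(hublike_rest) * HUBLIKE_BOOST
               + len(decoys) * DECOY_BOOST)
    n_edges = sum(len(nb) for nb in adj.values()) // 2
    max_edges = len(adj) * (len(adj) - 1) // 2
    goal = min(max(target - n_boost, n_edges), max_edges)
    attempts = 0
    while n_edges < goal and attempts < 200 * target:
        attempts += 1
        u = all_labels[rng.integers(len(all_labels))]
        v = all_labels[rng.integers(len(all_labels))]
        if u != v and v not in adj[u]:
            add_edge(u, v)
            n_edges += 1

    # extra attachment rounds for the planted sets, applied last so the
    # boost is an additive margin on the final degree scale
    for labels, boost in ((superhubs, SUPERHUB_BOOST),
                          (decoys, DECOY_BOOST),
                          (hublike_rest, HUBLIKE_BOOST)):
        for h in labels:
            non_nb = [u for u in all_labels if u != h and u not in adj[h]]
            k = min(boost, len(non_nb))
            if k > 0:
                for i in rng.choice(len(non_nb), size=k, replace=False):
                    add_edge(h, non_nb[i])

    edges = {(u, v) if u <= v else (v, u)
             for u, nbs in adj.items() for v in nbs}
    return Network(config.disease_ids[index], frozenset(adj), frozenset(edges))


def reference_isolation_plan(
    hublike: Sequence[str], superhubs: Sequence[str]
) -> dict[str, tuple[str, ...]]:
    """Isolation plan reproducing the reference screen arithmetic.

    Six candidates isolated in the expression layer, two of those also in
    the activation layer, and seventeen in the inhibition layer (five of
    the six plus twelve others, among them every super-hub except the
    first), so the screen removes 18 of 36 candidates and exactly one
    super-hub survives.
    """
    hublike = list(hublike)
    superhubs = list(superhubs)
    non_super = [p for p in hublike if p not in superhubs]
    if len(hublike) < 21 or len(non_super) < 18 or not superhubs:
        raise ValidationError(
            "candidate set too small for the reference isolation plan"
        )
    expression = tuple(non_super[-6:])
    activation = expression[:2]
    fillers = [p for p in non_super[:-6] if p not in superhubs][-10:]
    inhibition = tuple(list(expression[:5]) + superhubs[1:] + fillers)
    return {
        "expression": expression,
        "activation": activation,
        "inhibition": inhibition,
    }


def _resolved_plan(config: ScenarioConfig) -> dict[str, tuple[str, ...]]:
    if config.action_isolation_plan is not None:
        return {m: tuple(v) for m, v in config.action_isolation_plan.items()}
    try:
        return reference_isolation_plan(config.hublike_labels(), config.superhub_labels())
    except ValidationError:
        return {}


def generate_trio(config: ScenarioConfig) -> tuple[list[Network], Manifest]:
    """Generate all disease networks plus the ground-truth manifest."""
    networks = [generate_network(config, i) for i in range(config.n_networks)]
    plan = _resolved_plan(config)
    removed: set[str] = set()
    for labels in plan.values():
        removed |= set(labels)
    hublike = config.hublike_labels()
    core = [p for p in hublike if p not in removed]
    critical = [p for p in config.superhub_labels() if p in core]
    manifest = Manifest(
        disease_ids=tuple(config.disease_ids[: config.n_networks]),
        n_nodes=tuple(net.n_nodes for net in networks),
        n_edges=tuple(net.n_edges for net in networks),
        shared=tuple(config.shared_label_list()),
        hublike=tuple(hublike),
        superhubs=tuple(config.superhub_labels()),
        isolation_plan=plan,
        expected_funnel={
            "common": config.shared_labels,
            "hublike": config.hublike_shared,
            "core": len(core),
            "critical": len(critical),
        },
    )
    return networks, manifest


def generate_action_fixture(
    candidates: Sequence[str],
    isolation_plan: Mapping[str, Sequence[str]],
    seed: int = 0,
) -> list[ActionEdge]:
    """Build action edges realising a per-layer isolation plan exactly.

    In each layer the planned isolates get no incident edge while every
    other candidate gets at least one (a random chain plus a few extra
    random edges); edges never leave the candidate set.
    """
    cand = sorted(set(candidates))
    cand_set = set(cand)
    for mode, labels in isolation_plan.items():
        if mode not in ACTION_MODES:
            raise ValidationError(f"unknown action layer {mode!r}")
        outside = set(labels) - cand_set
        if outside:
            raise ValidationError(
                f"isolation plan for {mode!r} names non-candidates: {sorted(outside)}"
            )
    rng = np.random.default_rng((seed, _ACTION_STREAM))
    edges: list[ActionEdge] = []
    for mode in ACTION_MODES:
        isolates = set(isolation_plan.get(mode, ()))
        connected = [p for p in cand if p not in isolates]
        if len(connected) == 1:
            raise ValidationError(
                f"layer {mode!r}: a single connected candidate cannot receive "
                "an incident edge within the candidate set"
            )
        if len(connected) < 2:
            continue
        order = list(connected)
        rng.shuffle(order)
        pairs = list(zip(order, order[1:]))
        # a few extra random edges so layers are not bare chains
        existing = {(min(a, b), max(a, b)) for a, b in pairs}
        n_extra = len(connected) // 2
        for _ in range(n_extra):
            i, j = rng.choice(len(connected), size=2, replace=False)
            a, b = connected[i], connected[j]
            key = (min(a, b), max(a, b))
            if key not in existing:
                existing.add(key)
                pairs.append((a, b))
        for a, b in pairs:
            if rng.integers(2):
                a, b = b, a
            edges.append(ActionEdge(a, b, mode, directed=True))
    return edges


def write_scenario(config: ScenarioConfig, out_dir: str | Path) -> Manifest:
    """Generate a full scenario and write it to disk.

    Produces one STRING-style edge-list TSV per disease (with cosmetic
    confidence scores), an ``actions.tsv`` fixture, and ``manifest.yaml``.
    Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    networks, manifest = generate_trio(config)
    score_rng = np.random.default_rng((config.seed, _SCORE_STREAM))
    for net in networks:
        ordered = sorted(net.edges)
        scores = {
            e: round(0.4 + 0.599 * score_rng.random(), 3) for e in ordered
        }
        write_edge_list(net, out / f"{net.disease_id}.tsv",
                        scores=scores, header=True)
    fixture = generate_action_fixture(
        manifest.hublike, manifest.isolation_plan, seed=config.seed
    )
    write_action_table(fixture, out / "actions.tsv")
    manifest.write(out / "manifest.yaml")
    return manifest


def config_from_yaml(path: str | Path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from a flat YAML mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: scenario config must be a mapping")
    kwargs = dict(raw)
    for key in ("target_edges", "disease_ids"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "action_isolation_plan" in kwargs and kwargs["action_isolation_plan"]:
        kwargs["action_isolation_plan"] = {
            m: tuple(v) for m, v in kwargs["action_isolation_plan"].items()
        }
    try:
        return ScenarioConfig(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"{path}: bad scenario config: {exc}") from exc
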
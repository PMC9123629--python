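"""End-to-end screening funnel and report writing.

Stage order is fixed: per-disease centralities → cross-disease common set →
top-50% hub-like filter → action-map isolation screen (over the hub-like
common set) → top-10% common hubs → critical proteins (core ∩ hubs).  The
funnel counts are monotonically non-increasing across
common → hub-like → core, and the critical set is contained in both the
core and the common hub set; both invariants are asserted on every run.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import actionmap, screening
from .centrality import CentralityRecord, compute_all
from .errors import PpiScreenError, ValidationError
from .netio import (
    ACTION_MODES,
    ActionEdge,
    Network,
    read_action_table,
    read_string_links,
    write_node_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    """Everything the screening funnel produced, every stage retained."""

    tables: Mapping[str, tuple[CentralityRecord, ...]]
    common_set: screening.CommonSet
    hublike_common: frozenset[str]
    action_core: frozenset[str]
    common_hubs: frozenset[str]
    critical_set: frozenset[str]
    funnel_counts: tuple[tuple[str, int], ...]
    removed: Mapping[str, frozenset[str]]
    action_screen_applied: bool

    def summary(self) -> str:
        """Human-readable funnel summary."""
        lines = ["stage            count  members"]
        named = {
            "common": sorted(self.common_set.members),
            "hublike": sorted(self.hublike_common),
            "core": sorted(self.action_core),
            "hubs": sorted(self.common_hubs),
            "critical": sorted(self.critical_set),
        }
        stages = list(self.funnel_counts) + [("hubs", len(self.common_hubs))]
        for stage, count in stages:
            members = named.get(stage, [])
            shown = ", ".join(members[:8]) + (" ..." if len(members) > 8 else "")
            lines.append(f"{stage:<16} {count:>5}  {shown}")
        if not self.action_screen_applied:
            lines.append("(no action table supplied: isolation screen skipped)")
        return "\n".join(lines)


def screen_networks(
    networks: Sequence[Network],
    action_edges: Sequence[ActionEdge] | None = None,
    hub_pct: float = 10.0,
    hublike_pct: float = 50.0,
    layers: Sequence[str] = ACTION_MODES,
    tie_policy: str = "strict",
    hub_scope: str = "all",
) -> ScreenResult:
    """Run the full screening funnel on in-memory networks."""
    if len(networks) < 2:
        raise ValidationError("the screen requires at least two disease networks")
    tables = {net.disease_id: tuple(compute_all(net)) for net in networks}

    common = screening.common_proteins(networks)
    if not common.members:
        logger.warning("common protein set is empty; downstream stages are empty")
    hublike = screening.common_hublike(
        tables, common, percentile=hublike_pct,
        tie_policy=tie_policy, scope=hub_scope,
    )
    if action_edges is not None:
        amap = actionmap.build_action_map(hublike, action_edges)
        outcome = actionmap.screen_by_isolation(amap, tuple(layers))
        core = outcome.core
        removed = outcome.removed
        applied = True
    else:
        logger.info("no action table: core defaults to the hub-like common set")
        core = frozenset(hublike)
        removed = {}
        applied = False
    hubs = screening.common_hubs(
        tables, common, percentile=hub_pct,
        tie_policy=tie_policy, scope=hub_scope,
    )
    critical = actionmap.critical_proteins(core, hubs)
    funnel = (
        ("common", len(common.members)),
        ("hublike", len(hublike)),
        ("core", len(core)),
        ("critical", len(critical)),
    )
    assert len(common.members) >= len(hublike) >= len(core), "funnel must shrink"
    assert critical <= core and critical <= hubs, "critical set containment"
    return ScreenResult(
        tables=tables,
        common_set=common,
        hublike_common=frozenset(hublike),
        action_core=frozenset(core),
        common_hubs=frozenset(hubs),
        critical_set=frozenset(critical),
        funnel_counts=funnel,
        removed=removed,
        action_screen_applied=applied,
    )


def run_screen(
    network_paths: Mapping[str, str | Path],
    action_path: str | Path | None = None,
    hub_pct: float = 10.0,
    hublike_pct: float = 50.0,
    layers: Sequence[str] = ACTION_MODES,
    tie_policy: str = "strict",
    hub_scope: str = "all",
) -> ScreenResult:
    """Read network/action files and run the funnel.

    ``network_paths`` maps disease id → edge-list path (plain or STRING
    dialect, auto-detected).  Reader errors propagate with the disease id
    as stage context.
    """
    networks = []
    for disease, path in network_paths.items():
        try:
            networks.append(read_string_links(path, disease))
        except PpiScreenError as exc:
            raise type(exc)(f"[network {disease}] {exc}") from exc
    edges = None
    if action_path is not None:
        try:
            edges = read_action_table(action_path)
        except PpiScreenError as exc:
            raise type(exc)(f"[action table] {exc}") from exc
    return screen_networks(
        networks, edges, hub_pct=hub_pct, hublike_pct=hublike_pct,
        layers=layers, tie_policy=tie_policy, hub_scope=hub_scope,
    )


def make_report(result: ScreenResult, out_dir: str | Path) -> None:
    """Write the full funnel report to a directory, deterministically.

    Contents: per-disease node tables (3-decimal display CSV plus a
    full-precision variant), ``funnel_summary.csv``, ``screen_status.csv``
    (when the action screen ran) and one cross-disease centrality table per
    critical protein in the ``disease, degree, max_degree, BC, CC, stress``
    layout, degree shown next to the network maximum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for disease in sorted(result.tables):
        records = result.tables[disease]
        if records:
            write_node_table(records, out / f"{disease}_nodes.csv")
            write_node_table(records, out / f"{disease}_nodes_full.csv",
                             full_precision=True)
    with open(out / "funnel_summary.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["stage", "count", "members"])
        named = {
            "common": result.common_set.members,
            "hublike": result.hublike_common,
            "core": result.action_core,
            "hubs": result.common_hubs,
            "critical": result.critical_set,
        }
        rows = list(result.funnel_counts) + [("hubs", len(result.common_hubs))]
        for stage, count in rows:
            writer.writerow([stage, count, ";".join(sorted(named[stage]))])
    if result.action_screen_applied:
        outcome = actionmap.ScreenOutcome(result.removed, result.action_core)
        actionmap.write_screen_outcome(outcome, out / "screen_status.csv")
    if not result.critical_set:
        logger.info("empty critical set: no per-protein tables written")
    for protein in sorted(result.critical_set):
        path = out / f"critical_{protein}.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow([
                "disease", "degree", "max_degree", "betweenness", "closeness",
                "stress", "betweenness_full", "closeness_full",
            ])
            for disease in sorted(result.tables):
                records = result.tables[disease]
                by_node = {r.node: r for r in records}
                if protein not in by_node:
                    continue
                r = by_node[protein]
                max_deg = max(rec.degree for rec in records)
                writer.writerow([
                    disease, r.degree, max_deg, f"{r.betweenness:.3f}",
                    f"{r.closeness:.3f}", r.stress,
                    repr(r.betweenness), repr(r.closeness),
                ])
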
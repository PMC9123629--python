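"""Regulatory action-map construction and the isolation screen.

An action map is a multi-layer directed graph over a candidate protein set,
one layer per regulatory mode (activation, inhibition, expression).  The
screen removes every candidate that is *isolated* — has no incident edge in
either direction — in any selected layer; survivors form the core set.
Incidence is deliberately direction-agnostic: a candidate with only an
outgoing activation edge is still connected in the activation layer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .netio import ACTION_MODES, ActionEdge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActionMap:
    """Per-mode induced action subgraphs over a candidate set."""

    candidates: frozenset[str]
    layers: Mapping[str, tuple[ActionEdge, ...]]


@dataclass(frozen=True)
class ScreenOutcome:
    """Result of the isolation screen: removed candidates per layer + core."""

    removed: Mapping[str, frozenset[str]]
    core: frozenset[str]


def build_action_map(
    candidates: Iterable[str], edges: Sequence[ActionEdge]
) -> ActionMap:
    """Restrict action edges to the candidate set and split them by mode.

    Edges with any endpoint outside the candidate set are discarded (the
    count is logged).
    """
    cand = frozenset(candidates)
    layers: dict[str, list[ActionEdge]] = {m: [] for m in ACTION_MODES}
    discarded = 0
    for e in edges:
        if e.source in cand and e.target in cand:
            layers[e.mode].append(e)
        else:
            discarded += 1
    if discarded:
        logger.info(
            "discarded %d action edge(s) with endpoints outside the %d candidates",
            discarded, len(cand),
        )
    return ActionMap(cand, {m: tuple(v) for m, v in layers.items()})


def isolated_in_layer(amap: ActionMap, mode: str) -> frozenset[str]:
    """Candidates with zero incident edges (either direction) in a layer."""
    if mode not in amap.layers:
        raise ValidationError(
            f"unknown action layer {mode!r}; known layers: "
            f"{sorted(amap.layers)}"
        )
    touched = set()
    for e in amap.layers[mode]:
        touched.add(e.source)
        touched.add(e.target)
    return frozenset(amap.candidates - touched)


def screen_by_isolation(
    amap: ActionMap, modes: Iterable[str] = ACTION_MODES
) -> ScreenOutcome:
    """Remove candidates isolated in ANY selected layer; the rest is the core."""
    modes = tuple(modes)
    if not modes:
        raise ValidationError("screen_by_isolation requires at least one mode")
    removed = {m: isolated_in_layer(amap, m) for m in modes}
    union: set[str] = set()
    for s in removed.values():
        union |= s
    return ScreenOutcome(removed, frozenset(amap.candidates - union))


def critical_proteins(core: Iterable[str], hubs: Iterable[str]) -> frozenset[str]:
    """Intersection of the action-screen core with the common hub set."""
    return frozenset(core) & frozenset(hubs)


def write_screen_outcome(outcome: ScreenOutcome, path: str | Path) -> None:
    """Write a two-column CSV: protein, status in {core, removed:<mode>}.

    A protein isolated in several layers gets one row per layer, so the
    union of ``removed:*`` rows reconstructs the removal exactly.
    """
    rows: list[tuple[str, str]] = [(p, "core") for p in sorted(outcome.core)]
    for mode in sorted(outcome.removed):
        rows.extend((p, f"removed:{mode}") for p in sorted(outcome.removed[mode]))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["protein", "status"])
        writer.writerows(rows)
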
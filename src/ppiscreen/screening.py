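"""Degree-percentile hub selection and cross-disease set intersection.

Hub selection ranks nodes by degree only (BC/CC/stress are reported, never
filtered on).  The cut size for a percentile ``p`` over ``n`` nodes is
``max(1, round_half_up(p/100 * n))``.  In ``strict`` mode exactly that many
nodes are returned, ties at the boundary broken lexicographically by label;
``include_ties`` additionally admits every node tied with the last included
degree.

"Common hubs" across diseases demand membership in the top percentile of
*every* network (``scope="all"``); a relaxed ``scope="any"`` mode is exposed
because the prose convention differs between tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .centrality import CentralityRecord
from .errors import ValidationError
from .netio import Network


@dataclass(frozen=True)
class RankedSet:
    """Nodes selected by a degree percentile for one disease network."""

    disease_id: str
    percentile: float
    members: tuple[str, ...]
    cut_size: int


@dataclass(frozen=True)
class CommonSet:
    """Proteins present in every one of a group of disease networks."""

    diseases: tuple[str, ...]
    members: frozenset[str]


def _cut_size(n: int, percentile: float) -> int:
    return max(1, math.floor(percentile / 100.0 * n + 0.5))


def top_percent(
    records: Sequence[CentralityRecord],
    percentile: float,
    tie_policy: str = "strict",
    disease_id: str = "",
) -> RankedSet:
    """Select the top ``percentile``% of nodes by degree.

    ``tie_policy='strict'`` returns exactly the cut size after
    (degree desc, label asc) ordering; ``'include_ties'`` extends the
    selection to every node whose degree ties the last included one.
    """
    if not records:
        raise ValidationError("top_percent requires a non-empty record list")
    if not 0 < percentile <= 100:
        raise ValidationError(
            f"percentile must be in (0, 100], got {percentile}"
        )
    if tie_policy not in ("strict", "include_ties"):
        raise ValidationError(f"unknown tie policy {tie_policy!r}")
    ordered = sorted(records, key=lambda r: (-r.degree, r.node))
    k = _cut_size(len(ordered), percentile)
    members = [r.node for r in ordered[:k]]
    if tie_policy == "include_ties" and k < len(ordered):
        boundary = ordered[k - 1].degree
        for r in ordered[k:]:
            if r.degree == boundary:
                members.append(r.node)
            else:
                break
    return RankedSet(disease_id, percentile, tuple(members), k)


def common_proteins(networks: Sequence[Network]) -> CommonSet:
    """Intersection of node sets across at least two disease networks."""
    if len(networks) < 2:
        raise ValidationError(
            f"common_proteins requires >= 2 networks, got {len(networks)}"
        )
    members = frozenset.intersection(*(frozenset(n.nodes) for n in networks))
    return CommonSet(tuple(n.disease_id for n in networks), members)


def _percentile_members(
    tables: Mapping[str, Sequence[CentralityRecord]],
    percentile: float,
    tie_policy: str,
) -> dict[str, frozenset[str]]:
    return {
        disease: frozenset(
            top_percent(records, percentile, tie_policy, disease).members
        )
        for disease, records in tables.items()
    }


def _scoped_filter(
    common: CommonSet,
    per_disease: Mapping[str, frozenset[str]],
    scope: str,
) -> frozenset[str]:
    if scope == "all":
        return frozenset(
            p for p in common.members
            if all(p in members for members in per_disease.values())
        )
    if scope == "any":
        return frozenset(
            p for p in common.members
            if any(p in members for members in per_disease.values())
        )
    raise ValidationError(f"unknown hub scope {scope!r} (use 'all' or 'any')")


def common_hublike(
    tables: Mapping[str, Sequence[CentralityRecord]],
    common: CommonSet,
    percentile: float = 50.0,
    tie_policy: str = "strict",
    scope: str = "all",
) -> frozenset[str]:
    """Common proteins falling in the top ``percentile``% of every network."""
    return _scoped_filter(
        common, _percentile_members(tables, percentile, tie_policy), scope
    )


def common_hubs(
    tables: Mapping[str, Sequence[CentralityRecord]],
    common: CommonSet,
    percentile: float = 10.0,
    tie_policy: str = "strict",
    scope: str = "all",
) -> frozenset[str]:
    """Common proteins that are degree hubs (top 10% by default) everywhere."""
    return _scoped_filter(
        common, _percentile_members(tables, percentile, tie_policy), scope
    )
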
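"""Cross-contrast comparison: common up/down sets and Venn partitions.

The study design yields one DE result set per contrast (exercise vs
sedentary, in naive and in lesioned tissue).  This module intersects those
calls: proteins commonly regulated in the same direction across contrasts,
and a full Venn partition of a shared protein universe into disjoint
membership regions (including the "not enriched in any set" region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .de_analysis import DEResultSet

logger = logging.getLogger(__name__)


@dataclass
class VennPartition:
    """Disjoint membership regions over a protein universe.

    ``regions`` maps a tuple of set names (subset of ``set_names``, in input
    order; the empty tuple is the not-enriched region) to the protein ids
    belonging to exactly those sets.
    """

    set_names: list[str]
    regions: dict[tuple[str, ...], set[str]]
    universe_size: int

    @property
    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def not_enriched(self) -> set[str]:
        return self.regions.get((), set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(names) if names else "none",
             "count": len(ids),
             "protein_ids": ";".join(sorted(ids))}
            for names, ids in self.regions.items()
        ]
        return pd.DataFrame(rows, columns=["region", "count", "protein_ids"])


def common_sets(a: DEResultSet, b: DEResultSet) -> tuple[set[str], set[str]]:
    """Proteins called up in both result sets, and down in both."""
    if not (a.protein_ids & b.protein_ids):
        logger.warning("result sets share no proteins; common sets are empty")
    return a.up_ids & b.up_ids, a.down_ids & b.down_ids


def de_membership_sets(results: list[DEResultSet]) -> dict[str, set[str]]:
    """Expand DE result sets into named up/down id sets (one pair per contrast)."""
    out: dict[str, set[str]] = {}
    for res in results:
        out[f"{res.contrast.name}_up"] = res.up_ids
        out[f"{res.contrast.name}_down"] = res.down_ids
    return out


def venn_partition(results, universe) -> VennPartition:
    """Partition ``universe`` by membership across the input sets.

    ``results`` is either a list of DEResultSets (expanded to per-contrast
    up/down sets) or a mapping name -> id set.  Every universe protein lands
    in exactly one region; a member outside the universe is an error.
    """
    if isinstance(results, dict):
        named = {k: set(v) for k, v in results.items()}
    else:
        named = de_membership_sets(list(results))
    universe = set(universe)
    for name, ids in named.items():
        stray = ids - universe
        if stray:
            raise ValueError(
                f"set {name!r} contains proteins outside the universe: {sorted(stray)[:5]}"
            )
    names = list(named)
    regions: dict[tuple[str, ...], set[str]] = {}
    for pid in universe:
        key = tuple(n for n in names if pid in named[n])
        regions.setdefault(key, set()).add(pid)
    return VennPartition(set_names=names, regions=regions, universe_size=len(universe))


def shared_universe(results: list[DEResultSet]) -> set[str]:
    """Intersection of the (post-filter) protein universes of all contrasts."""
    it = iter(results)
    universe = set(next(it).protein_ids)
    for res in it:
        universe &= res.protein_ids
    return universe
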
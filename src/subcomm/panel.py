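"""Strain panels and subcommunity compositions.

A *composition* is a vertex of the binary hypercube over a fixed, ordered
panel of nondegrader strains.  The obligate degrader is implicit: it is
present in every subcommunity and never appears as a feature.  Richness
therefore counts the implicit degrader, so a "two-member" community is the
degrader plus one nondegrader.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

#: Presence/absence vector over the panel order (1 = strain present).
Membership = tuple[int, ...]


@dataclass(frozen=True)
class StrainPanel:
    """Ordered panel of nondegrader strain labels plus the obligate degrader.

    Parameters
    ----------
    strain_ids
        Unique labels of the nondegrader strains, in the fixed order used by
        every membership vector, design matrix and output table.
    degrader_id
        Label of the obligate degrader present in every subcommunity.
    """

    strain_ids: tuple[str, ...]
    degrader_id: str = "degrader"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain_ids", tuple(str(s) for s in self.strain_ids))
        if len(self.strain_ids) < 1:
            raise ValueError("panel needs at least one nondegrader strain")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("strain_ids must be unique")
        if self.degrader_id in self.strain_ids:
            raise ValueError("degrader_id must not appear among strain_ids")

    @property
    def p(self) -> int:
        return len(self.strain_ids)

    def index_of(self, strain: str) -> int:
        try:
            return self.strain_ids.index(strain)
        except ValueError:
            raise KeyError(f"strain {strain!r} not in panel") from None

    def membership_of(self, strains: Iterable[str]) -> Membership:
        """Membership vector for a set of present nondegrader strains."""
        idx = {self.index_of(s) for s in strains}
        return tuple(1 if i in idx else 0 for i in range(self.p))

    def strains_present(self, membership: Membership) -> tuple[str, ...]:
        return tuple(s for s, m in zip(self.strain_ids, membership) if m)


def default_panel(p: int = 8, degrader_id: str = "degrader") -> StrainPanel:
    """Generic panel with strain labels NS1..NSp (study scale: p=8)."""
    return StrainPanel(tuple(f"NS{i + 1}" for i in range(p)), degrader_id)


def validate_membership(membership: Sequence[int], p: int) -> Membership:
    m = tuple(int(v) for v in membership)
    if len(m) != p:
        raise ValueError(f"membership length {len(m)} != panel size {p}")
    if any(v not in (0, 1) for v in m):
        raise ValueError(f"membership values must be 0/1, got {m}")
    return m


def richness(membership: Sequence[int]) -> int:
    """Community richness: nondegraders present plus the implicit degrader."""
    return int(sum(membership)) + 1


def mask_of(membership: Sequence[int]) -> int:
    """Bitmask encoding (bit i = strain i present)."""
    mask = 0
    for i, v in enumerate(membership):
        if v:
            mask |= 1 << i
    return mask


def membership_of_mask(mask: int, p: int) -> Membership:
    return tuple((mask >> i) & 1 for i in range(p))


def enumerate_compositions(panel: StrainPanel, richness_level: int) -> list[Membership]:
    """All compositions at a given richness, in lexicographic membership order.

    Richness counts the implicit degrader, so ``richness_level`` compositions
    carry ``richness_level - 1`` nondegraders; there are C(p, richness-1) of
    them and summing over richness 1..p+1 recovers the full 2^p design.
    """
    p = panel.p
    if not 1 <= richness_level <= p + 1:
        raise ValueError(f"richness {richness_level} out of range [1, {p + 1}]")
    k = richness_level - 1
    out = []
    for idx in combinations(range(p), k):
        present = set(idx)
        out.append(tuple(1 if i in present else 0 for i in range(p)))
    out.sort()
    assert len(out) == comb(p, k)
    return out


def enumerate_pool(panel: StrainPanel, richness_levels: Iterable[int]) -> list[Membership]:
    """Compositions pooled over several richness levels (sorted, deduplicated)."""
    pool: set[Membership] = set()
    for r in richness_levels:
        pool.update(enumerate_compositions(panel, r))
    return sorted(pool)
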
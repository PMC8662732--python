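"""Regulator connectivity: trio ranking and key-regulator selection.

A regulator's target set is its network neighbourhood (other regulators
count as targets; self is excluded).  Trios are scored by the number of
unique non-member genes covered by the union of the three target sets, with
ties broken toward lower redundancy (genes covered by two or more members)
and then lexicographic member order.  Key regulators are chosen by greedy
maximum coverage: repeatedly pick the regulator adding the most uncovered
genes, stopping early when no pick adds anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .network import CoAssocNetwork


@dataclass
class RegulatorTrio:
    members: tuple[str, str, str]
    union_targets: int
    redundancy: int


@dataclass
class KeyRegulatorSet:
    members: list[str]
    covered_genes: set[str]
    marginal_gains: list[int]

    @property
    def coverage(self) -> int:
        return len(self.covered_genes)


def target_sets(network: CoAssocNetwork) -> dict[str, frozenset]:
    """Map each flagged regulator to its set of network neighbours.

    Isolated regulators keep an empty set.  Raises if no node is flagged.
    """
    regs = network.regulators()
    if not regs:
        raise ValueError("network has no flagged regulators")
    return {r: frozenset(network.neighbors(r)) for r in regs}


def rank_trios(target_map: dict[str, frozenset], top_k: int = 10) -> list[RegulatorTrio]:
    """Exhaustively rank all regulator trios by unique coverage.

    Score = |T(a) u T(b) u T(c) \\ {a, b, c}|; ties by lower redundancy
    (count of genes, members excluded, reached by >= 2 of the three), then
    lexicographic member ids.  Returns the top ``top_k``.
    """
    regs = sorted(target_map)
    if len(regs) < 3:
        raise ValueError("need at least 3 regulators to form trios")
    trios = []
    for a, b, c in combinations(regs, 3):
        members = {a, b, c}
        ta, tb, tc = target_map[a], target_map[b], target_map[c]
        union = (ta | tb | tc) - members
        multi = ((ta & tb) | (ta & tc) | (tb & tc)) - members
        trios.append(RegulatorTrio((a, b, c), len(union), len(multi)))
    trios.sort(key=lambda t: (-t.union_targets, t.redundancy, t.members))
    return trios[:top_k]


def select_key_regulators(
    target_map: dict[str, frozenset], k: int = 5, exhaustive: bool = False
) -> KeyRegulatorSet:
    """Pick up to ``k`` regulators maximising joint target coverage.

    Greedy by default: each pick is the regulator adding the most uncovered
    genes (ties toward the larger total target set, then lexicographic id);
    stops early when no pick has positive gain.  ``exhaustive=True``
    enumerates every k-subset (guarded to <= 25 regulators) and returns the
    best by coverage with the same tie-breaks applied to the sorted members.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(target_map):
        raise ValueError(f"k={k} exceeds the {len(target_map)} regulators")

    clean = {r: frozenset(t) - {r} for r, t in target_map.items()}

    if exhaustive:
        if len(clean) > 25:
            raise ValueError("exhaustive selection is limited to 25 regulators")
        best = None
        for subset in combinations(sorted(clean), k):
            union = frozenset().union(*(clean[r] for r in subset)) - set(subset)
            key = (-len(union), subset)
            if best is None or key < best[0]:
                best = (key, subset, union)
        _, subset, union = best
        # report gains in greedy-equivalent order over the chosen subset
        covered: set = set()
        gains, ordered = [], []
        remaining = list(subset)
        while remaining:
            pick = min(
                sorted(remaining),
                key=lambda r: (-len(clean[r] - covered), -len(clean[r]), str(r)),
            )
            remaining.remove(pick)
            gains.append(len(clean[pick] - covered))
            covered |= clean[pick]
            ordered.append(pick)
        return KeyRegulatorSet(ordered, covered - set(subset), gains)

    covered: set = set()
    members: list[str] = []
    gains: list[int] = []
    candidates = set(clean)
    for _ in range(k):
        best_r, best_key = None, None
        for r in sorted(candidates):
            gain = len(clean[r] - covered - set(members) - {r})
            key = (-gain, -len(clean[r]), str(r))
            if best_key is None or key < best_key:
                best_r, best_key = r, key
        gain = -best_key[0]
        if gain <= 0:
            break
        members.append(best_r)
        covered |= clean[best_r]
        gains.append(gain)
        candidates.discard(best_r)
    covered -= set(members)
    return KeyRegulatorSet(members, covered, gains)


def trio_table(trios: list[RegulatorTrio]) -> pd.DataFrame:
    """Trio ranking as a table (members joined by ' - ', unique counts)."""
    return pd.DataFrame(
        {
            "trio": [" - ".join(t.members) for t in trios],
            "n_unique_interactions": [t.union_targets for t in trios],
            "redundancy": [t.redundancy for t in trios],
        }
    )
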
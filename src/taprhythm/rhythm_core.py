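"""Cyclic rhythms as binary cue patterns on an isochronous pulse grid.

A rhythm is a cyclic sequence of ``N`` isochronous pulses, ``K`` of which are
*cued* (sounded as targets to tap).  The class of interest is the nondegenerate
well-formed rhythms: patterns generated by circularly stacking a single
interval, characterized by Myhill's property (every generic interval — the
count of intervening cues plus one — comes in exactly two specific sizes, the
count of intervening pulses plus one).  These patterns have exactly two
interonset-interval (IOI) sizes, distributed as evenly as possible, and cover
both familiar duple/triple cycles and the odd cycles typical of aksak music.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import gcd
from functools import reduce
from typing import Iterable, Sequence

__all__ = [
    "Rhythm",
    "ioi_sequence",
    "has_myhill_property",
    "is_nondegenerate_wellformed",
    "canonical_rotation",
    "enumerate_wf_rhythms",
    "complement",
    "rotate",
]


@dataclass(frozen=True)
class Rhythm:
    """A cyclic binary cue pattern over ``N`` isochronous pulses.

    Parameters
    ----------
    indicator:
        Length-``N`` sequence of 0/1; 1 marks a cued pulse.  Pulse indices are
        0-based; within a cycle, pulse ``n`` occurs at time ``n * 234`` ms.
    id:
        Stable text label.  Auto-generated as ``"N{N}K{K}"`` when omitted;
        the enumerator assigns suffixed labels such as ``"N8K5a"``.
    """

    indicator: tuple
    id: str = field(default="", compare=False)

    def __post_init__(self):
        ind = tuple(int(v) for v in self.indicator)
        if len(ind) < 1 or any(v not in (0, 1) for v in ind):
            raise ValueError("indicator must be a nonempty 0/1 sequence")
        object.__setattr__(self, "indicator", ind)
        if not self.id:
            object.__setattr__(self, "id", f"N{self.N}K{self.K}")

    @property
    def N(self) -> int:
        return len(self.indicator)

    @property
    def K(self) -> int:
        return sum(self.indicator)

    @property
    def cue_positions(self) -> tuple:
        return tuple(i for i, v in enumerate(self.indicator) if v)

    @classmethod
    def from_string(cls, s: str, id: str = "") -> "Rhythm":
        """Parse a rhythm from its '10110...' indicator string."""
        return cls(tuple(int(c) for c in s.strip()), id=id)

    @classmethod
    def from_iois(cls, iois: Sequence[int], id: str = "") -> "Rhythm":
        """Build a rhythm starting on a cue from its IOI sequence."""
        ind = []
        for d in iois:
            if d < 1:
                raise ValueError("IOIs must be positive")
            ind.append(1)
            ind.extend([0] * (d - 1))
        return cls(tuple(ind), id=id)

    def to_string(self) -> str:
        return "".join(str(v) for v in self.indicator)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.id}:{self.to_string()}"


def ioi_sequence(r: Rhythm) -> tuple:
    """Circular gaps (in pulses) from each cue to the next.

    Starts at the first cue at/after pulse 0; the K gaps sum to N.
    """
    cues = r.cue_positions
    if not cues:
        raise ValueError("empty rhythm")
    K, N = len(cues), r.N
    return tuple(((cues[(j + 1) % K] - cues[j]) % N) or N for j in range(K))


def _specific_sizes(r: Rhythm, g: int) -> set:
    """Distinct specific sizes (pulse counts) of generic interval ``g``."""
    cues = r.cue_positions
    K, N = len(cues), r.N
    return {(cues[(j + g) % K] - cues[j]) % N for j in range(K)}


def has_myhill_property(r: Rhythm) -> bool:
    """True iff every generic interval g = 1..K-1 has exactly two specific sizes."""
    K = r.K
    if K < 2 or K >= r.N:
        return False
    return all(len(_specific_sizes(r, g)) == 2 for g in range(1, K))


def is_primitive(r: Rhythm) -> bool:
    """True iff the cue set is not confined to a proper sub-grid of the cycle.

    Equivalent to gcd of the IOI sequence being 1.  A pattern whose IOIs share
    a common divisor d > 1 is an augmentation of a rhythm on N/d pulses and has
    no generator coprime with N, so it is not well-formed on the N-pulse cycle.
    """
    return reduce(gcd, ioi_sequence(r)) == 1


def is_nondegenerate_wellformed(r: Rhythm) -> bool:
    """Nondegenerate well-formedness: Myhill's property on a primitive pattern.

    Myhill's property (two specific sizes per generic interval) characterizes
    nondegenerate well-formed patterns generated by an interval coprime with
    N; the primitivity condition excludes sub-grid patterns such as (4 2) in a
    6-pulse cycle, which satisfy the bare cardinality check but have no such
    generator.
    """
    return has_myhill_property(r) and is_primitive(r)


def rotate(r: Rhythm, s: int) -> Rhythm:
    """Rotate so that old pulse ``s`` becomes new pulse 0."""
    N = r.N
    s %= N
    return Rhythm(r.indicator[s:] + r.indicator[:s], id=r.id)


def canonical_rotation(r: Rhythm) -> Rhythm:
    """Rotation starting on a cue whose IOI sequence is lexicographically largest.

    This places the small IOIs as late in the cycle as possible, e.g. the
    (N=8, K=5) well-formed rhythm always canonicalizes to (1 0 1 0 1 1 0 1),
    i.e. IOIs (2 2 1 2 1).
    """
    iois = ioi_sequence(r)
    K = len(iois)
    best = max(tuple(iois[j:] + iois[:j]) for j in range(K))
    out = Rhythm.from_iois(best, id=r.id)
    assert out.N == r.N
    return out


def necklace_key(r: Rhythm) -> tuple:
    """Canonical representative of the rotation class (for dedup/equality)."""
    ind = r.indicator
    N = r.N
    return max(ind[i:] + ind[:i] for i in range(N))


def complement(r: Rhythm) -> Rhythm:
    """Swap cued and uncued pulses."""
    if r.K == 0 or r.K == r.N:
        raise ValueError("complement would be all-cued or all-uncued")
    return Rhythm(tuple(1 - v for v in r.indicator), id=f"{r.id}~" if r.id else "")


def enumerate_wf_rhythms(
    n_range: tuple = (3, 13),
    k_range: tuple = (2, 11),
    max_ioi: int = 5,
) -> list:
    """All rotation-distinct nondegenerate well-formed rhythms in the given ranges.

    Returns canonical rotations, deterministically ordered by (N, K, IOI
    sequence); ids are assigned as ``"N{N}K{K}"`` plus a letter suffix within
    each (N, K) class.  With the defaults this yields the 91-rhythm universe
    (3-13 pulses, 2-11 cues, no IOI larger than 5 pulses).
    """
    n_lo, n_hi = n_range
    k_lo, k_hi = k_range
    if n_lo > n_hi or k_lo > k_hi:
        raise ValueError("empty N or K range")
    found = []
    for N in range(n_lo, n_hi + 1):
        seen = set()
        for K in range(max(2, k_lo), min(k_hi, N - 1) + 1):
            # fix a cue at pulse 0: every rotation class has such a representative
            for rest in itertools.combinations(range(1, N), K - 1):
                r = Rhythm((1,) + tuple(1 if i + 1 in set(rest) else 0
                                        for i in range(N - 1)))
                key = necklace_key(r)
                if key in seen:
                    continue
                seen.add(key)
                if max(ioi_sequence(r)) > max_ioi:
                    continue
                if is_nondegenerate_wellformed(r):
                    found.append(canonical_rotation(r))
    found.sort(key=lambda r: (r.N, r.K, ioi_sequence(r)))
    out = []
    by_nk: dict = {}
    for r in found:
        idx = by_nk.setdefault((r.N, r.K), [])
        label = f"N{r.N}K{r.K}{chr(ord('a') + len(idx))}"
        idx.append(r)
        out.append(Rhythm(r.indicator, id=label))
    return out
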
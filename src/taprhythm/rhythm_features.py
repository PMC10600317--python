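"""Rhythm-level structural predictors.

Each function maps a cyclic rhythm to a scalar summary used as a regression
predictor: circular-statistics measures (evenness, balance), entropies of the
interval content, Carey's coherence and sameness quotients, and simple size
descriptors.  All are invariant under rotation of the rhythm.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from .rhythm_core import Rhythm, ioi_sequence

__all__ = [
    "evenness",
    "balance",
    "ioi_entropy",
    "interval_entropy",
    "coherence_failures",
    "coherence_quotient",
    "sameness_quotient",
    "duple_triple",
    "mean_ioi",
    "rhythm_feature_table",
]


def _centroid(r: Rhythm) -> complex:
    """Mean of unit vectors at the cue angles 2*pi*t/N."""
    t = np.array(r.cue_positions)
    return complex(np.mean(np.exp(2j * np.pi * t / r.N)))


def evenness(r: Rhythm) -> float:
    """Similarity of the cue set to a perfectly even K-point set, in [0, 1].

    Magnitude of the mean, over cues j = 0..K-1 in temporal order at pulses
    t_j, of unit vectors at angle 2*pi*(t_j/N - j/K): each cue is compared
    against its slot in an ideal isochronous template, and the phase of the
    template is optimized out by taking the magnitude.  Equals 1 exactly when
    the cues are equally spaced; e.g. (1 1 0) scores 0.866 and (1 1 0 0)
    scores 0.707.
    """
    K = r.K
    if K < 2:
        raise ValueError("evenness requires at least two cues")
    t = np.array(r.cue_positions)
    j = np.arange(K)
    return float(abs(np.mean(np.exp(2j * np.pi * (t / r.N - j / K)))))


def balance(r: Rhythm) -> float:
    """One minus the distance of the cues' centre of mass from the circle centre.

    1 means perfectly balanced (centroid at the centre, e.g. antipodal cues);
    0 means all cues coincide on one pulse.  Equivalent to the circular
    variance of the cue distribution.
    """
    if r.K < 1:
        raise ValueError("balance requires at least one cue")
    return float(1.0 - abs(_centroid(r)))


def ioi_entropy(r: Rhythm) -> float:
    """Shannon entropy (bits) of the distribution of consecutive-cue IOIs."""
    counts = pd.Series(ioi_sequence(r)).value_counts().to_numpy()
    return float(_shannon(counts, base=2))


def _directed_intervals(r: Rhythm):
    """All K*(K-1) directed inter-cue intervals as (generic, specific) pairs."""
    cues = r.cue_positions
    K, N = len(cues), r.N
    for g in range(1, K):
        for j in range(K):
            yield g, (cues[(j + g) % K] - cues[j]) % N


def interval_entropy(r: Rhythm) -> float:
    """Shannon entropy (bits) of all directed inter-cue intervals modulo the period.

    Considers the full multiset of K*(K-1) intervals, not just consecutive
    ones; e.g. (1 0 0 1 0 0 1 0 0 1 0) has multiset {2:1, 3:3, 5:2, 6:2, 8:3, 9:1}.
    """
    if r.K < 2:
        raise ValueError("interval entropy requires at least two cues")
    sizes = [s for _, s in _directed_intervals(r)]
    counts = pd.Series(sizes).value_counts().to_numpy()
    return float(_shannon(counts, base=2))


def coherence_failures(r: Rhythm) -> int:
    """Count of interval pairs where a smaller generic interval has a larger span.

    A failure is an unordered pair of directed intervals (a, b) with
    generic(a) < generic(b) but specific(a) > specific(b): counting cues then
    misranks the temporal spans.
    """
    by_generic: dict = {}
    for g, s in _directed_intervals(r):
        by_generic.setdefault(g, []).append(s)
    generics = sorted(by_generic)
    f = 0
    for gi, g in enumerate(generics):
        a = np.sort(np.array(by_generic[g]))
        for h in generics[gi + 1:]:
            b = np.array(by_generic[h])
            f += int(np.sum(len(a) - np.searchsorted(a, b, side="right")))
    return f


@lru_cache(maxsize=None)
def max_coherence_failures(K: int, max_pulses: int = 13) -> int:
    """Largest failure count achievable by any K-onset pattern with N <= max_pulses.

    Brute-force maximization (rotation classes are covered by fixing a cue at
    pulse 0); cached per (K, max_pulses).
    """
    best = 0
    for N in range(K + 1, max_pulses + 1):
        for rest in itertools.combinations(range(1, N), K - 1):
            ind = [0] * N
            ind[0] = 1
            for i in rest:
                ind[i] = 1
            best = max(best, coherence_failures(Rhythm(tuple(ind))))
    return best


def coherence_quotient(r: Rhythm) -> float:
    """Carey's coherence quotient: 1 - failures / max possible failures, in [0, 1].

    Undefined (NaN) for K < 3, where no two generic interval classes exist.
    """
    if r.K < 3:
        return float("nan")
    return 1.0 - coherence_failures(r) / max_coherence_failures(r.K)


def sameness_quotient(r: Rhythm) -> float:
    """Carey's sameness quotient: fewer distinct spans per generic interval is higher.

    1 - sum over generic intervals of (distinct specific sizes - 1), divided
    by the maximum (K-1)^2: there are K-1 generic classes, each with at most
    K distinct sizes.  Every nondegenerate well-formed rhythm has exactly two
    sizes per generic interval, so the numerator is K-1 and the quotient is a
    deterministic increasing function of K.
    """
    K = r.K
    if K < 2:
        raise ValueError("sameness quotient requires at least two cues")
    by_generic: dict = {}
    for g, s in _directed_intervals(r):
        by_generic.setdefault(g, set()).add(s)
    extra = sum(len(sizes) - 1 for sizes in by_generic.values())
    return 1.0 - extra / (K - 1) ** 2


def duple_triple(r: Rhythm) -> int:
    """1 if the cycle length is divisible by 2 or 3 (metricizable), else 0."""
    return int(r.N % 2 == 0 or r.N % 3 == 0)


def mean_ioi(r: Rhythm) -> float:
    """Mean interonset interval between cues, N/K pulses."""
    if r.K < 1:
        raise ValueError("mean IOI requires at least one cue")
    return r.N / r.K


def rhythm_feature_table(rhythms) -> pd.DataFrame:
    """One row of rhythm-level predictors per rhythm, indexed by rhythm id."""
    rows = []
    for r in rhythms:
        rows.append({
            "rhythm_id": r.id,
            "N": r.N,
            "K": r.K,
            "mean_ioi": mean_ioi(r),
            "evenness": evenness(r),
            "balance": balance(r),
            "ioi_ent": ioi_entropy(r),
            "int_ent": interval_entropy(r),
            "cq": coherence_quotient(r),
            "sq": sameness_quotient(r),
            "duple_triple": duple_triple(r),
        })
    return pd.DataFrame(rows).set_index("rhythm_id")
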
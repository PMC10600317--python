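"""Pulse-level structural predictors.

Each function maps a rhythm to a length-N vector: one value per pulse, cued or
uncued.  All are equivariant under rotation (rotating the rhythm rotates the
output), which is what makes them usable as within-rhythm predictors when the
starting cue is randomized across performances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rhythm_core import Rhythm

__all__ = [
    "markov",
    "edge",
    "EDGE_KERNEL",
    "mean_offset",
    "projected_centroid",
    "apm",
    "seq_exp",
    "SEQ_EXP_PARAMS",
    "povel_accents",
    "pulse_feature_table",
]


def markov(r: Rhythm, k: int) -> np.ndarray:
    """Optimal order-k Markov cue probability at each pulse.

    For pulse n, take the length-k binary context over the previous k pulses
    (circularly) and return the proportion of the context's occurrences in the
    cycle that are followed by a cue.  For the tresillo (1 0 0 1 0 0 1 0) and
    k = 2 this is (1/3, 0, 1/3, 1, 0, 1/3, 1, 0).
    """
    N = r.N
    if not 1 <= k < N:
        raise ValueError("context length must be in 1..N-1")
    ind = r.indicator
    contexts = [tuple(ind[(n - k + i) % N] for i in range(k)) for n in range(N)]
    followed: dict = {}
    total: dict = {}
    for n, c in enumerate(contexts):
        total[c] = total.get(c, 0) + 1
        followed[c] = followed.get(c, 0) + ind[n]
    # every pulse's own context occurs in the cycle by construction
    return np.array([followed[c] / total[c] for c in contexts])


# Edge-detector kernel: derivative of a Gaussian (scale in pulses) with a
# small temporal shift and a per-sample DC correction, calibrated once so the
# pattern (0 0 1 1 0 0) yields edge values (0.00, 0.22, 0.15, 0.27, 0.20,
# 0.00); see docs/methods.md for the calibration and the (provable) necessity
# of the shift and DC terms.
EDGE_KERNEL = {
    "amplitude": 9.836453,
    "shift": -0.0071177,
    "sigma": 0.3604842,
    "dc": -0.0249998,
}


def _wrapped_edge_kernel(N: int, params: dict) -> np.ndarray:
    A = params["amplitude"]
    mu = params["shift"]
    sigma = params["sigma"]
    d = np.arange(N, dtype=float)
    k = np.zeros(N)
    for j in range(-6, 7):  # lattice sum; sigma << N so terms vanish fast
        t = d + j * N - mu
        k += A * t * np.exp(-t * t / (2.0 * sigma * sigma))
    return k + params["dc"]


def edge(r: Rhythm, params: dict = EDGE_KERNEL) -> np.ndarray:
    """Edge strength at each pulse: boundaries of cue groups and of gaps.

    Absolute circular convolution of the bipolar cue signal (indicator - 1/2)
    with a derivative-of-Gaussian kernel.  The bipolar encoding treats cued
    and uncued pulses symmetrically, so the result is exactly invariant under
    complementation (swapping cues and gaps) for any kernel.  High values mark
    the starts and ends of clusters; within a two-cue cluster the second cue
    scores higher, matching Povel's accent on the end of a two-group.
    """
    N = r.N
    y = np.array(r.indicator, dtype=float) - 0.5
    k = _wrapped_edge_kernel(N, params)
    idx = (np.arange(N)[:, None] - np.arange(N)[None, :]) % N
    return np.abs(k[idx] @ y)


def mean_offset(r: Rhythm) -> np.ndarray:
    """Normalized mean temporal offset between each pulse and the cues.

    For pulse n: the sum of forward circular distances to all cues minus the
    sum of backward circular distances, divided by K*N so values lie in
    [-1, 1].  High near the ends of cue clusters, low near their starts.
    """
    N, K = r.N, r.K
    if K < 1:
        raise ValueError("mean offset requires at least one cue")
    cues = np.array(r.cue_positions)
    n = np.arange(N)[:, None]
    fwd = (cues[None, :] - n) % N
    bwd = (n - cues[None, :]) % N
    return (fwd.sum(axis=1) - bwd.sum(axis=1)) / (K * N)


def projected_centroid(r: Rhythm) -> np.ndarray:
    """Signed projection of the cue centroid onto each pulse's diameter, in [-1, 1].

    Pulses near the circular mean of the cues score up to +|centroid|; the
    antipodal pulses score the negative.  Identically zero for perfectly
    balanced rhythms.
    """
    if r.K < 1:
        raise ValueError("projected centroid requires at least one cue")
    t = np.array(r.cue_positions)
    c = np.mean(np.exp(2j * np.pi * t / r.N))
    angles = 2 * np.pi * np.arange(r.N) / r.N
    return np.real(c * np.exp(-1j * angles))


def apm(r: Rhythm, lags=None) -> np.ndarray:
    """Metrical-accent weight from a circular autocorrelation phase matrix.

    For each lag k (default 1..N//2), walk the cycle in steps of k from each
    pulse (lcm(N, k)/k steps closes the orbit) and accumulate the product of
    cue indicators at successive steps; normalize each lag by its term count
    and average over lags.  Pulses in phase with strongly supported
    isochronous beats score high.
    """
    N = r.N
    if N < 2:
        raise ValueError("autocorrelation phase matrix requires N >= 2")
    if lags is None:
        lags = range(1, N // 2 + 1)
    x = np.array(r.indicator, dtype=float)
    out = np.zeros(N)
    n_lags = 0
    for k in lags:
        steps = np.lcm(N, k) // k
        acc = np.zeros(N)
        idx = np.arange(N)
        for i in range(steps):
            acc += x[(idx + i * k) % N] * x[(idx + (i + 1) * k) % N]
        out += acc / steps
        n_lags += 1
    return out / max(n_lags, 1)


# Shape constants for the sequential-expectation predictor: the run-length
# gain sets how quickly longer isochronous cue runs strengthen the
# expectation of a continuation, the IOI decay how quickly wider spacings
# weaken it.  Chosen once as moderate defaults; config-exposed.
SEQ_EXP_PARAMS = {"run_gain": 0.5, "ioi_decay": 0.5}


def seq_exp(r: Rhythm, params: dict = SEQ_EXP_PARAMS) -> np.ndarray:
    """Expectation that each pulse continues an isochronous run of cues.

    For pulse n and spacing d, let m be the largest count such that pulses
    n-d, n-2d, ..., n-m*d are all cued (capped at one full cycle).  Runs of
    m >= 2 contribute (1 - run_gain**(m-1)) * ioi_decay**(d-1): increasing in
    run length, decreasing in spacing.  Contributions sum over spacings.
    """
    for key in ("run_gain", "ioi_decay"):
        if key not in params:
            raise ValueError(
                f"seq_exp requires the '{key}' shape constant in params")
    a, b = params["run_gain"], params["ioi_decay"]
    if not (0 < a < 1) or not (0 < b <= 1):
        raise ValueError("run_gain must be in (0,1) and ioi_decay in (0,1]")
    N = r.N
    ind = r.indicator
    out = np.zeros(N)
    for n in range(N):
        for d in range(1, N // 2 + 1):
            m = 0
            while m < N // d and ind[(n - (m + 1) * d) % N]:
                m += 1
            if m >= 2:
                out[n] += (1.0 - a ** (m - 1)) * b ** (d - 1)
    return out


def povel_accents(r: Rhythm):
    """Povel's perceptual accents as three binary vectors (iso, start, end).

    iso: cue with uncued neighbours on both sides; end: last cue of a run of
    two or more; start: first cue of a run of three or more.  All circular.
    """
    N = r.N
    ind = r.indicator
    if r.K < 1:
        raise ValueError("accents require at least one cue")
    iso = np.zeros(N, dtype=int)
    start = np.zeros(N, dtype=int)
    end = np.zeros(N, dtype=int)
    if r.K == N:  # one unbroken run covering the cycle: no boundaries
        return iso, start, end
    for n in range(N):
        if not ind[n]:
            continue
        prev, nxt = ind[(n - 1) % N], ind[(n + 1) % N]
        if not prev and not nxt:
            iso[n] = 1
        if prev and not nxt:
            end[n] = 1
        if not prev and nxt:
            # run length from n forward
            m = 1
            while ind[(n + m) % N]:
                m += 1
            if m >= 3:
                start[n] = 1
    return iso, start, end


def pulse_feature_table(rhythms, edge_params: dict = EDGE_KERNEL,
                        seq_exp_params: dict = SEQ_EXP_PARAMS) -> pd.DataFrame:
    """One row per (rhythm, pulse) with every pulse-level predictor.

    Columns: cue, apm, seq_exp, edge, mean_offset, proj_cent, markov2,
    markov3, markov4, iso_accent, start_accent, end_accent.
    """
    frames = []
    for r in rhythms:
        iso, start, end = povel_accents(r)
        df = pd.DataFrame({
            "rhythm_id": r.id,
            "n": np.arange(r.N),
            "cue": np.array(r.indicator, dtype=int),
            "apm": apm(r),
            "seq_exp": seq_exp(r, seq_exp_params),
            "edge": edge(r, edge_params),
            "mean_offset": mean_offset(r),
            "proj_cent": projected_centroid(r),
            "markov2": markov(r, 2) if r.N > 2 else np.nan,
            "markov3": markov(r, 3) if r.N > 3 else np.nan,
            "markov4": markov(r, 4) if r.N > 4 else np.nan,
            "iso_accent": iso,
            "start_accent": start,
            "end_accent": end,
        })
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
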
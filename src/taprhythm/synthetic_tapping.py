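"""Synthetic tapping cohorts with known ground truth.

Generates tap logs with the statistical structure the downstream analysis
assumes: per-pulse tap occurrence from a logistic model driven by structural
predictors with cue interactions and crossed participant/rhythm effects;
velocities from a censored normal (MIDI ceiling 127); signed asynchronies from
a truncated normal with distinct cued/uncued means; occasional double taps a
few tens of milliseconds after a real tap.  The generative model mirrors the
observation families fitted by :mod:`taprhythm.inference`, so simulated
cohorts support end-to-end and parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .rhythm_core import Rhythm, enumerate_wf_rhythms
from .pulse_features import pulse_feature_table
from .tap_metrics import PULSE_MS, PULSES_PER_PERFORMANCE, HALF_WINDOW_MS, Performance

__all__ = ["SimConfig", "simulate_performance", "simulate_cohort"]


@dataclass
class SimConfig:
    """Cohort-shape and observation-model parameters for the simulator.

    Defaults emulate a large tapping experiment: 111 participants, the 91-rhythm
    well-formed universe split into four disjoint sets (23/23/23/22), each
    assigned rhythm performed twice in randomized block order, 129 pulses per
    30-s performance at a 234-ms interonset interval, randomized starting cue,
    MIDI velocities censored at 127, and double taps about 15 or 60 ms after
    a genuine tap.  The tap-probability coefficients are illustrative values
    at the order of magnitude of typical estimates (cue about 2 on the
    log-odds scale, structural effects below 0.5), not estimates.
    """

    n_participants: int = 111
    rhythm_sets: int = 4
    repetitions: int = 2
    seed: int = 0
    # tap-probability model (log-odds scale, raw predictor units)
    beta_intercept: float = -2.0
    beta_cue: float = 2.0
    beta_features: Dict[str, float] = field(
        default_factory=lambda: {"proj_cent": 0.45, "edge": 0.4, "markov2": 0.3})
    beta_cue_features: Dict[str, float] = field(
        default_factory=lambda: {"proj_cent": -0.2, "edge": -0.5, "markov2": -0.3})
    sd_participant: float = 0.5
    sd_rhythm: float = 0.5
    sd_cue_participant: float = 0.78
    sd_cue_rhythm: float = 0.96
    # velocity model (MIDI units)
    vel_mean: float = 90.0
    vel_sd: float = 15.0
    vel_participant_sd: float = 21.7
    vel_ceiling: int = 127
    # asynchrony model (ms)
    delta_mean_cued: float = -9.0
    delta_mean_uncued: float = 4.8
    delta_sd: float = 30.0
    # double taps
    double_tap_prob: float = 0.034
    double_tap_offsets: Tuple[int, int] = (15, 60)

    def validate(self):
        if self.n_participants < 1 or self.rhythm_sets < 1 or self.repetitions < 1:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.double_tap_prob <= 1:
            raise ValueError("double_tap_prob must be a probability")
        for name in ("sd_participant", "sd_rhythm", "sd_cue_participant",
                     "sd_cue_rhythm", "vel_sd", "delta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if set(self.beta_cue_features) - set(self.beta_features):
            raise ValueError("cue-interaction features must be a subset of "
                             "beta_features")


def _linear_predictor(config: SimConfig, feats: pd.DataFrame) -> np.ndarray:
    """Log-odds of a tap at each pulse row, before random effects."""
    eta = np.full(len(feats), config.beta_intercept)
    cue = feats["cue"].to_numpy(dtype=float)
    eta += config.beta_cue * cue
    for name, b in config.beta_features.items():
        eta += b * feats[name].to_numpy(dtype=float)
    for name, b in config.beta_cue_features.items():
        eta += b * cue * feats[name].to_numpy(dtype=float)
    return eta


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_performance(config: SimConfig, rhythm: Rhythm,
                         feats: pd.DataFrame, rng: np.random.Generator,
                         participant: str = "p000", perf_num: int = 1,
                         repetition: int = 1, start_cue: Optional[int] = None,
                         participant_effect: float = 0.0,
                         rhythm_effect: float = 0.0,
                         cue_participant_effect: float = 0.0,
                         cue_rhythm_effect: float = 0.0,
                         vel_participant_effect: float = 0.0) -> Performance:
    """Simulate one 30-s performance of ``rhythm``.

    ``feats`` must be the pulse-feature rows for this rhythm, indexed 0..N-1.
    The starting cue is drawn uniformly from the rhythm's cues when not given.
    """
    config.validate()
    N = rhythm.N
    if start_cue is None:
        start_cue = int(rng.choice(rhythm.cue_positions))
    elif not rhythm.indicator[start_cue]:
        raise ValueError("start_cue must index a cued pulse")

    eta_pulse = _linear_predictor(config, feats)
    seq = np.arange(PULSES_PER_PERFORMANCE)
    pos = (start_cue + seq) % N
    cued = np.array([rhythm.indicator[p] for p in pos], dtype=float)
    eta = (eta_pulse[pos] + participant_effect + rhythm_effect
           + cued * (cue_participant_effect + cue_rhythm_effect))
    tapped = rng.random(len(seq)) < expit(eta)
    idx = np.nonzero(tapped)[0]

    mean_delta = np.where(cued[idx] > 0, config.delta_mean_cued,
                          config.delta_mean_uncued)
    # draw half a millisecond inside the window so integer rounding of tap
    # times never crosses a window boundary
    bound = HALF_WINDOW_MS - 0.5
    deltas = _truncated_normal(rng, mean_delta, config.delta_sd,
                               -bound, bound, len(idx))
    times = idx * float(PULSE_MS) + deltas
    # nothing can be tapped before the performance starts
    keep = times >= 0
    idx, deltas, times = idx[keep], deltas[keep], times[keep]
    vel_mu = config.vel_mean + vel_participant_effect
    vels = np.clip(np.round(rng.normal(vel_mu, config.vel_sd, len(idx))),
                   1, config.vel_ceiling).astype(int)

    taps = list(zip(times.tolist(), vels.tolist()))
    # double taps: a bounce shortly after the true tap, placed only where it
    # stays in the same pulse window with worse timing, so assignment
    # discards exactly the injected echoes
    n_doubles = 0
    for t, v, d in zip(times, vels, deltas):
        if rng.random() >= config.double_tap_prob:
            continue
        off = float(rng.choice(config.double_tap_offsets))
        if d + off < HALF_WINDOW_MS - 0.5 and abs(d + off) > abs(d):
            taps.append((float(t + off), int(max(1, v // 2))))
            n_doubles += 1
    taps.sort()
    perf = Performance(participant=participant, rhythm_id=rhythm.id,
                       perf_num=perf_num, repetition=repetition,
                       start_cue=start_cue, taps=taps)
    perf.n_double_taps = n_doubles
    return perf


def simulate_cohort(config: SimConfig, rhythms: Optional[Sequence[Rhythm]] = None):
    """Simulate a full cohort; returns (tap-log table, ground-truth record).

    Participants are assigned one of the disjoint rhythm sets; each assigned
    rhythm is performed ``repetitions`` times, with the performance order
    randomized within each repetition block.  The tap log has columns
    participant, rhythm_id, perf_num, repetition, start_cue, t_ms, velocity
    (integer milliseconds); the ground truth records the configuration, the
    sampled random effects, and the injected double-tap count.
    """
    config.validate()
    if rhythms is None:
        rhythms = enumerate_wf_rhythms()
    rhythms = list(rhythms)
    feats = pulse_feature_table(rhythms)
    feat_by_rhythm = {rid: df.reset_index(drop=True)
                      for rid, df in feats.groupby("rhythm_id", sort=False)}

    root = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    # disjoint rhythm sets of near-equal size, in enumeration order
    set_sizes = [len(rhythms) // config.rhythm_sets
                 + (1 if i < len(rhythms) % config.rhythm_sets else 0)
                 for i in range(config.rhythm_sets)]
    if min(set_sizes) == 0:
        raise ValueError("fewer rhythms than rhythm sets")
    sets, k = [], 0
    for size in set_sizes:
        sets.append(rhythms[k:k + size])
        k += size

    rhythm_eff = {r.id: master.normal(0, config.sd_rhythm) for r in rhythms}
    cue_rhythm_eff = {r.id: master.normal(0, config.sd_cue_rhythm) for r in rhythms}

    rows = []
    truth_participants = {}
    total_doubles = 0
    part_seeds = root.spawn(config.n_participants)
    for p in range(config.n_participants):
        rng = np.random.default_rng(part_seeds[p])
        pid = f"p{p:03d}"
        p_eff = rng.normal(0, config.sd_participant)
        cue_p_eff = rng.normal(0, config.sd_cue_participant)
        vel_p_eff = rng.normal(0, config.vel_participant_sd)
        truth_participants[pid] = {
            "set": p % config.rhythm_sets,
            "intercept": p_eff, "cue": cue_p_eff, "velocity": vel_p_eff,
        }
        assigned = sets[p % config.rhythm_sets]
        perf_num = 0
        for rep in range(1, config.repetitions + 1):
            order = rng.permutation(len(assigned))
            for j in order:
                r = assigned[j]
                perf_num += 1
                perf = simulate_performance(
                    config, r, feat_by_rhythm[r.id], rng,
                    participant=pid, perf_num=perf_num, repetition=rep,
                    participant_effect=p_eff, rhythm_effect=rhythm_eff[r.id],
                    cue_participant_effect=cue_p_eff,
                    cue_rhythm_effect=cue_rhythm_eff[r.id],
                    vel_participant_effect=vel_p_eff)
                total_doubles += perf.n_double_taps
                for t, v in perf.taps:
                    rows.append((pid, r.id, perf_num, rep, perf.start_cue,
                                 int(round(t)), int(v)))
    taps = pd.DataFrame(rows, columns=["participant", "rhythm_id", "perf_num",
                                       "repetition", "start_cue", "t_ms",
                                       "velocity"])
    truth = {
        "config": asdict(config),
        "rhythm_ids": [r.id for r in rhythms],
        "rhythm_effects": rhythm_eff,
        "cue_rhythm_effects": cue_rhythm_eff,
        "participants": truth_participants,
        "n_double_taps": total_doubles,
    }
    return taps, truth
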
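import numpy as np
import pytest

from taprhythm.rhythm_core import enumerate_wf_rhythms
from taprhythm.rhythm_features import rhythm_feature_table
from taprhythm.pulse_features import pulse_feature_table
from taprhythm.synthetic_tapping import SimConfig, simulate_cohort
from taprhythm.cli_io import taps_to_performances, build_joined_table


@pytest.fixture(scope="session")
def universe():
    """The default enumerated well-formed rhythm universe."""
    return enumerate_wf_rhythms()


@pytest.fixture(scope="session")
def universe_features(universe):
    return rhythm_feature_table(universe)


@pytest.fixture(scope="session")
def universe_pulse_features(universe):
    return pulse_feature_table(universe)


@pytest.fixture(scope="session")
def small_cohort(universe):
    """A compact simulated cohort with fixed-effects-only ground truth."""
    rhythms = universe[:8]
    config = SimConfig(n_participants=6, rhythm_sets=2, repetitions=1, seed=7,
                       sd_participant=0.0, sd_rhythm=0.0,
                       sd_cue_participant=0.0, sd_cue_rhythm=0.0)
    taps, truth = simulate_cohort(config, rhythms)
    return {"rhythms": rhythms, "config": config, "taps": taps, "truth": truth}


@pytest.fixture(scope="session")
def small_joined(small_cohort):
    rhythms = small_cohort["rhythms"]
    by_id = {r.id: r for r in rhythms}
    performances = taps_to_performances(small_cohort["taps"])
    joined = build_joined_table(performances, by_id,
                                rhythm_feature_table(rhythms),
                                pulse_feature_table(rhythms))
    return {"joined": joined, "performances": performances, "by_id": by_id}
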
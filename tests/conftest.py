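from datetime import date, timedelta

import pandas as pd
import pytest

from routinesense import CleaningConfig, EventLog, binarize_power, classify_gaps
from routinesense.synthetic_data import PRESETS, simulate


def make_log(rows, residence_id="R1", localized=True, first_day=None, last_day=None):
    """Build an EventLog from (timestamp, room, kind, channel, value) tuples."""
    df = pd.DataFrame(
        [(pd.Timestamp(ts), residence_id, room, kind, channel, float(v))
         for ts, room, kind, channel, v in rows],
        columns=["timestamp", "residence_id", "room", "sensor_kind",
                 "channel", "value"],
    )
    return EventLog(df, residence_id=residence_id, localized=localized,
                    first_day=first_day, last_day=last_day)


def motion(ts, room="kitchen"):
    return (ts, room, "motion", "", 1.0)


def power(ts, channel="kettle", value=0.06, room="kitchen"):
    return (ts, room, "power", channel, value)


@pytest.fixture(scope="session")
def rupert_sim():
    """90-day simulated stream for the rigid-routine archetype, cleaned."""
    profile, artifacts = PRESETS["rupert"]()
    log, truth = simulate(profile, artifacts, n_days=90, seed=11)
    cfg = CleaningConfig()
    clean = binarize_power(log, cfg)
    gaps = classify_gaps(clean, cfg=cfg)
    return {"raw": log, "clean": clean, "gaps": gaps, "truth": truth,
            "cleaning": cfg}


@pytest.fixture(scope="session")
def jacqui_sim():
    """140-day simulated stream for the travelling archetype (travel blocks)."""
    profile, artifacts = PRESETS["jacqui"]()
    log, truth = simulate(profile, artifacts, n_days=140, seed=11)
    cfg = CleaningConfig()
    clean = binarize_power(log, cfg)
    gaps = classify_gaps(clean, cfg=cfg)
    return {"raw": log, "clean": clean, "gaps": gaps, "truth": truth,
            "cleaning": cfg}
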
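import numpy as np
import pandas as pd
import pytest

from dyadcoord import CouplingConfig, SessionMetadata, simulate_session


def metadata(pair_id="P001", condition="Baseline", bg_round=1, **kw):
    return SessionMetadata(
        pair_id=pair_id,
        condition=condition,
        bg_round=bg_round,
        time_before_bg_round=0.0 if bg_round == 1 else kw.pop("elapsed", 300.0),
        **kw,
    )


@pytest.fixture(scope="session")
def session_zero():
    """One zero-coupling synthetic session, shared across tests."""
    return simulate_session(metadata(), CouplingConfig(seed=0), 150.0, seed=42)


@pytest.fixture(scope="session")
def session_coupled():
    cfg = CouplingConfig(
        pupil_coupling=6.0,
        gaze_follow_prob=0.8,
        motion_coupling=3.0,
        prosody_coupling=3.0,
        turn_adaptation=0.6,
        lsm_overlap=1.0,
        seed=0,
    )
    return simulate_session(metadata(), cfg, 150.0, seed=43)


def segments_df(rows):
    """rows: (speaker, onset, offset[, pitch, intensity, syllables])"""
    out = []
    for r in rows:
        spk, on, off = r[:3]
        pitch = r[3] if len(r) > 3 else 180.0
        inten = r[4] if len(r) > 4 else 60.0
        syll = r[5] if len(r) > 5 else max(1, int(round(5 * (off - on))))
        out.append(
            {
                "speaker": spk,
                "onset": float(on),
                "offset": float(off),
                "mean_pitch": pitch,
                "mean_intensity": inten,
                "n_syllables": syll,
            }
        )
    return pd.DataFrame(out)


def fixation_df(rows):
    """rows: (onset, offset, aoi[, valid])"""
    return pd.DataFrame(
        [
            {
                "onset": float(r[0]),
                "offset": float(r[1]),
                "aoi": r[2],
                "valid": bool(r[3]) if len(r) > 3 else True,
            }
            for r in rows
        ]
    )
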
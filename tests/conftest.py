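import numpy as np
import pandas as pd
import pytest

import meghfo as m


@pytest.fixture(scope="session")
def layout():
    return m.default_layout()


@pytest.fixture(scope="session")
def small_layout(layout):
    """First four channels of the default layout (all central-left)."""
    return m.SensorRegionMap(layout.table.iloc[:4].copy().reset_index(drop=True))


@pytest.fixture(scope="session")
def one_channel_layout(layout):
    return m.SensorRegionMap(layout.table.iloc[:1].copy().reset_index(drop=True))


@pytest.fixture(scope="session")
def noise_recording(one_channel_layout):
    """60 s of default background noise on one channel (seeded)."""
    return m.generate_background(one_channel_layout, 1200.0, 60.0, seed=11)


def make_rate_table(
    layout, rates_by_channel, subject_id="s1", class_label="ripple",
    minutes=10.0,
):
    """Rate table over the full layout with given per-channel rates."""
    rows = []
    for _, lrow in layout.table.iterrows():
        for cls in ("ripple", "fast_ripple"):
            rate = (
                rates_by_channel.get(lrow["channel_label"], 0.0)
                if cls == class_label else 0.0
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "visit_id": "v1",
                    "channel_label": lrow["channel_label"],
                    "region": lrow["region"],
                    "class_label": cls,
                    "rate": rate,
                    "recording_minutes": minutes,
                }
            )
    return pd.DataFrame(rows)


def region_rate_table(layout, region_rates, subject_id="s1",
                      class_label="ripple", minutes=10.0, jitter=None):
    """Rate table with one rate per region (optionally jittered per channel)."""
    rng = np.random.default_rng(jitter) if jitter is not None else None
    rates = {}
    for region, rate in region_rates.items():
        for ch in layout.channels_in_region(region):
            r = rate if rng is None else max(0.0, rate * (1 + 0.2 * rng.standard_normal()))
            rates[ch] = r
    return make_rate_table(layout, rates, subject_id, class_label, minutes)
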
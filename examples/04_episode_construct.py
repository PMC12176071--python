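"""The episode construct on a hand-made patient history.

A diagnosis is an episode of illness from the first encounter to the last
encounter plus half the diagnosis's contact-free interval; encounter gaps
larger than the interval split episodes, and chronic codes never close.
"""

import pandas as pd

import ehrdiv as ed

contacts = pd.DataFrame(
    {
        "pseudo_id": ["p"] * 5,
        "date": pd.to_datetime(
            ["2019-01-10", "2019-02-10", "2019-09-01", "2018-03-01", "2017-06-15"]
        ),
        "icpc": ["R05", "R05", "R05", "T90", "T90"],
        "episode_key": [""] * 5,
    }
)
rx = pd.DataFrame(
    {
        "pseudo_id": ["p"],
        "date": pd.to_datetime(["2019-02-12"]),
        "atc": ["R05DA04"],
        "icpc_indication": ["R05"],
    }
)
records = pd.DataFrame(
    {
        "pseudo_id": [],
        "episode_key": [],
        "icpc": [],
        "start_date": pd.Series([], dtype="datetime64[ns]"),
        "end_date": pd.Series([], dtype="datetime64[ns]"),
        "chronic": pd.Series([], dtype=bool),
    }
)

episodes = ed.episodes_construct(
    contacts,
    rx,
    records,
    analysis_year=2019,
    lookback_years=2,
    interval_map={"R05": 90},
    default_interval=90,
    chronic_codes=frozenset({"T90"}),
)
print(episodes.to_string(index=False))

# Two cough episodes: Jan 10 - Mar 29 (the Feb prescription counts as an
# encounter; end = Feb 12 + 45 days) and a second one in September, since the
# gap exceeds the 90-day contact-free interval.  The chronic diabetes code
# forms one open-ended episode from its first encounter in the lookback.
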
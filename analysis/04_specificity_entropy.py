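"""Neural specificity to LVP and its entropy coherence, per channel.

Computes each channel's contrastive specificity map against the session LVP,
reduces it to a normalised entropy series, writes per-channel summaries and
the event/non-event entropy partition keyed to the event series from the
previous step.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from sgcoflux.entropy import entropy_series, event_partition, summarize_entropy
from sgcoflux.errors import InsufficientDataError
from sgcoflux.events import EventSeries
from sgcoflux.io import read_session, read_spikes_csv
from sgcoflux.pipeline import AnalysisParams
from sgcoflux.specificity import make_bins, specificity_map


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.dir)
    config = json.loads((out / "config.json").read_text())
    duration = config["cohort"]["session_duration"]
    params = AnalysisParams()

    ent_rows, evt_rows = [], []
    for animal in config["animals"]:
        session = read_session(out / f"{animal}.h5")
        trains = read_spikes_csv(out / f"{animal}.spikes.csv", duration)
        bins = make_bins(session.lvp, params.n_bins, params.lo_pct, params.hi_pct)

        events = {}
        for stat in params.statistics:
            f = out / f"{animal}.{stat.lower()}.events.csv"
            if f.exists():
                df = pd.read_csv(f)
                events[stat] = EventSeries(
                    indicator=df["event"].to_numpy(np.int8),
                    timestamps=df["timestamp"].to_numpy(float),
                    intervals=[],
                    T=np.nan,
                    C=np.nan,
                    ER=np.nan,
                    statistic=stat,
                )

        for tr in trains:
            spec = specificity_map(tr, session.lvp, bins, params.spec_window, params.step)
            es = entropy_series(spec)
            try:
                s = summarize_entropy(es)
            except InsufficientDataError:
                continue
            ent_rows.append(
                {
                    "animal_id": animal,
                    "group": session.group,
                    "channel": tr.channel_id,
                    "entropy_mean": s.entropy_mean,
                    "entropy_std": s.entropy_std,
                }
            )
            for stat, ev in events.items():
                p = event_partition(es, ev)
                if p.partial:
                    continue
                for event_type, m, sd in (
                    ("event", p.inside_mean, p.inside_std),
                    ("non_event", p.outside_mean, p.outside_std),
                ):
                    evt_rows.append(
                        {
                            "animal_id": animal,
                            "group": session.group,
                            "channel": tr.channel_id,
                            "statistic": stat,
                            "event_type": event_type,
                            "baseline_entropy": s.entropy_mean,
                            "entropy_mean": m,
                            "entropy_std": sd,
                        }
                    )
        print(f"{animal}: {sum(r['animal_id'] == animal for r in ent_rows)} channel summaries")

    pd.DataFrame(ent_rows).to_csv(out / "entropy.csv", index=False)
    pd.DataFrame(evt_rows).to_csv(out / "event_entropy.csv", index=False)
    print(f"wrote {out / 'entropy.csv'} and {out / 'event_entropy.csv'}")


if __name__ == "__main__":
    main()
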
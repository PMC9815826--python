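"""Detect multi-unit spikes on every channel of every simulated session.

Runs the competitive adaptive-threshold detector, screens channel quality,
writes per-session spike CSVs, and reports recall/precision against the
generator's ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from sgcoflux.io import read_ground_truth, read_session, write_spikes_csv
from sgcoflux.pipeline import ChannelQualityRule, exclude_channels
from sgcoflux.spikes import DetectorParams, detect_spikes


def match_fraction(true_times, det_times, tol=1e-3):
    used = np.zeros(det_times.size, dtype=bool)
    matched = 0
    for t in true_times:
        if det_times.size == 0:
            break
        d = np.abs(det_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            matched += 1
    return matched


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.dir)
    config = json.loads((out / "config.json").read_text())

    for animal in config["animals"]:
        session = read_session(out / f"{animal}.h5")
        truth = read_ground_truth(out / f"{animal}.truth.json")
        trains, pols, counts = [], [], []
        for c, trace in enumerate(session.voltage.traces):
            det = detect_spikes(np.asarray(trace, float), session.voltage.fs, DetectorParams())
            det.train.channel_id = c
            trains.append(det.train)
            pols.append(det.polarity)
            counts.append(det.train.n_spikes)
        session = exclude_channels(session, ChannelQualityRule(), np.array(counts))
        keep = session.voltage.channel_mask
        kept = [(tr, p) for tr, p in zip(trains, pols) if keep[tr.channel_id]]
        write_spikes_csv(out / f"{animal}.spikes.csv", [t for t, _ in kept], [p for _, p in kept])

        n_true = n_det = n_match = 0
        for tr in trains:
            tt = truth.true_spikes[tr.channel_id]
            n_true += tt.size
            n_det += tr.n_spikes
            n_match += match_fraction(tt, tr.times)
        print(
            f"{animal}: {n_det} detected / {n_true} true "
            f"(recall {n_match / n_true:.3f}, precision {n_match / n_det:.3f}), "
            f"{int(keep.sum())}/{keep.size} channels kept"
        )


if __name__ == "__main__":
    main()
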
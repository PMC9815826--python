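"""Simulate a synthetic control/HF cohort and write sessions + ground truth.

Writes per-animal HDF5 sessions (voltage + LVP) and ground-truth JSON
sidecars under the output directory, plus a config echo consumed by the
downstream numbered scripts.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from sgcoflux.io import write_ground_truth, write_session
from sgcoflux.synthetic import CohortConfig, generate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-control", type=int, default=3)
    ap.add_argument("--n-hf", type=int, default=3)
    ap.add_argument("--duration", type=float, default=1200.0)
    ap.add_argument("--fs-voltage", type=float, default=2500.0)
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(
        n_control=args.n_control,
        n_hf=args.n_hf,
        session_duration=args.duration,
        fs_voltage=args.fs_voltage,
        seed=args.seed,
    )
    cohort = generate_cohort(cfg)
    ids = []
    for session, truth in cohort:
        write_session(out / f"{session.animal_id}.h5", session)
        write_ground_truth(out / f"{session.animal_id}.truth.json", truth)
        ids.append(session.animal_id)
        print(
            f"{session.animal_id} ({session.group}): "
            f"{sum(t.size for t in truth.true_spikes)} true spikes, "
            f"{len(truth.true_event_intervals)} true events"
        )
    (out / "config.json").write_text(
        json.dumps({"cohort": asdict(cfg), "animals": ids}, indent=2)
    )
    print(f"wrote {len(ids)} sessions to {out}")


if __name__ == "__main__":
    main()
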
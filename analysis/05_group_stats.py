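"""Group comparisons: event rates, entropy, and event entropy.

Scalar normality-gated tests for the per-animal event rates; linear mixed
models for the channel-nested entropy summaries and the event/non-event
entropy partition. Results print in (beta, +/-CI, d_RM, p) format and land in
stats.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sgcoflux.errors import InsufficientDataError
from sgcoflux.stats import compare_scalar_by_group, fit_entropy_lme, fit_event_entropy_lme


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.dir)
    rows = []

    er = pd.read_csv(out / "er.csv")
    for stat in sorted(er["statistic"].unique()):
        sub = er[er["statistic"] == stat]
        try:
            res = compare_scalar_by_group(sub["ER"].to_numpy(), sub["group"].to_numpy())
        except InsufficientDataError as e:
            print(f"ER_{stat}: skipped ({e})")
            continue
        print(
            f"ER_{stat}: control {res.group_means[0]:.5f} vs HF {res.group_means[1]:.5f} "
            f"evts/s ({res.test_name}: p={res.p:.4f}, d={res.effect_d:.2f})"
        )
        rows.append(
            {"comparison": f"ER_{stat}", "model": res.test_name, "beta": np.nan,
             "ci95": np.nan, "effect": res.effect_d, "p": res.p}
        )

    ent = pd.read_csv(out / "entropy.csv")
    for outcome in ("entropy_mean", "entropy_std"):
        try:
            res = fit_entropy_lme(ent, outcome=outcome)
        except InsufficientDataError as e:
            print(f"{outcome}: skipped ({e})")
            continue
        b, ci, d_rm, p = res.report()
        print(f"{outcome} ~ group: ({b:+.4f}, +/-{ci:.4f}, {d_rm:.2f}, p={p:.4f})")
        rows.append(
            {"comparison": f"{outcome}_group", "model": "lme", "beta": b,
             "ci95": ci, "effect": d_rm, "p": p}
        )

    evt = pd.read_csv(out / "event_entropy.csv")
    if len(evt):
        for outcome in ("entropy_mean", "entropy_std"):
            try:
                res = fit_event_entropy_lme(evt, outcome=outcome)
            except InsufficientDataError as e:
                print(f"event {outcome}: skipped ({e})")
                continue
            b, ci, d_rm, p = res.report()
            print(f"event {outcome} ~ event_type: ({b:+.4f}, +/-{ci:.4f}, {d_rm:.2f}, p={p:.4g})")
            rows.append(
                {"comparison": f"event_{outcome}_eventtype", "model": "lme", "beta": b,
                 "ci95": ci, "effect": d_rm, "p": p}
            )

    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False)
    print(f"wrote {out / 'stats.csv'}")


if __name__ == "__main__":
    main()
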
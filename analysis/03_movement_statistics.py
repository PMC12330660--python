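#!/usr/bin/env python
"""Tracklet statistics: speed vs size, coordination epochs, KS comparisons.

Reads the reconstructed ground tracks and fitted sizes from 02, extracts
>= 5 s tracklets, and computes (a) the size-quartile speed comparison,
(b) the per-frame fast-animal count with coordination epochs, and (c) the
participant vs non-participant size comparison.  Writes
results/stats/{tracklets,ks_results,coordination_epochs,fast_counts}.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from urbanrat.tracks import (detect_coordination, extract_and_filter_tracklets,
                             instantaneous_speeds, participant_size_comparison,
                             quartile_speed_comparison, tracklet_speed)

FIT = Path("results/fit")
OUT = Path("results/stats")
FRAME_RATE = 30.0
SMOOTH = 9          # 0.3 s median filter: per-frame jitter rivals the step size
FAST_PERCENTILE = 90  # "fast" = top decile of instantaneous speeds


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    gdf = pd.read_csv(FIT / "ground_tracks.csv")
    sizes = pd.read_csv(FIT / "sizes.csv").set_index("track_id")["relative_size"]
    tracks = {tid: df for tid, df in gdf.groupby("track_id")}
    tracklets = extract_and_filter_tracklets(tracks, FRAME_RATE,
                                             relative_sizes=sizes.to_dict())
    print(f"{len(tracklets)} tracklets of >= 5 s (from {len(tracks)} raw tracks)")
    pd.DataFrame([{
        "tracklet": t.id, "track_id": t.track_id, "duration_s": t.duration,
        "median_speed": t.median_speed, "relative_size": t.relative_size,
        "median_speed_smoothed": tracklet_speed(t, SMOOTH),
    } for t in tracklets]).to_csv(OUT / "tracklets.csv", index=False)

    ks_rows = []
    if len(tracklets) >= 8:
        ks = quartile_speed_comparison(tracklets, smooth_window=SMOOTH)
        print(f"speed, lower vs upper size quartile: D = {ks.statistic:.3f}, "
              f"p = {ks.pvalue:.3g}  ({ks.method}, n = {ks.n1}/{ks.n2})")
        ks_rows.append({"comparison": "speed_lower_vs_upper_size_quartile",
                        "D": ks.statistic, "p": ks.pvalue,
                        "n1": ks.n1, "n2": ks.n2})

    all_speeds = np.concatenate([instantaneous_speeds(t, SMOOTH)
                                 for t in tracklets])
    threshold = float(np.percentile(all_speeds, FAST_PERCENTILE))
    counts, epochs = detect_coordination(tracklets, speed_threshold=threshold,
                                         frame_rate=FRAME_RATE,
                                         smooth_window=SMOOTH)
    counts.rename_axis("frame").reset_index().to_csv(OUT / "fast_counts.csv",
                                                     index=False)
    pd.DataFrame([{
        "start": e.start, "end": e.end, "peak_count": e.peak_count,
        "participants": ";".join(sorted(e.participants)),
    } for e in epochs]).to_csv(OUT / "coordination_epochs.csv", index=False)
    print(f"{len(epochs)} coordination epochs (>= 3 animals above the "
          f"{FAST_PERCENTILE}th-percentile speed, {threshold:.2f} units/s)")

    if epochs:
        try:
            ks = participant_size_comparison(tracklets, epochs)
            print(f"size, participants vs non-participants: "
                  f"D = {ks.statistic:.3f}, p = {ks.pvalue:.3g}")
            ks_rows.append({"comparison": "size_participants_vs_nonparticipants",
                            "D": ks.statistic, "p": ks.pvalue,
                            "n1": ks.n1, "n2": ks.n2})
        except ValueError as exc:
            print(f"participant comparison skipped: {exc}")
    pd.DataFrame(ks_rows).to_csv(OUT / "ks_results.csv", index=False)


if __name__ == "__main__":
    main()
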
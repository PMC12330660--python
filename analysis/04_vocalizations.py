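#!/usr/bin/env python
"""Vocal analyses: bouts, F0 features, environment loudness, feature space.

Reads the annotated streams from 01, groups syllables into bouts (250 ms
rule), tracks each syllable's fundamental frequency, summarizes bouts as
median F0 +/- sd, measures the park/subway level difference in dB, and
projects syllables into the duration-frequency plane against the packaged
illustrative reference boxes.  Writes results/vocal/*.csv and a
feature-space figure.
"""

from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd

from urbanrat import bioacoustics as ba
from urbanrat.io import read_regions, read_wav

DATA = Path("results/data")
OUT = Path("results/vocal")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    fs, park = read_wav(DATA / "park.wav")
    _, subway = read_wav(DATA / "subway.wav")
    diff = ba.level_difference_db(subway, park)
    print(f"subway vs park level difference: {diff:+.2f} dB "
          f"(~{10 ** (diff / 20):.1f}x amplitude)")
    pd.DataFrame([{"comparison": "subway_vs_park",
                   "level_difference_db": diff}]).to_csv(
        OUT / "level_difference.csv", index=False)

    ann = pd.read_csv(DATA / "park_syllables.csv")
    cfg = ba.SpectrogramConfig(sample_rate=fs)
    syllables = []
    for r in ann.itertuples():
        s = ba.Syllable(onset=r.onset_s, offset=r.offset_s, label=r.label)
        chunk = park[int(s.onset * fs):int(s.offset * fs)]
        try:
            track = ba.estimate_f0(chunk, cfg, (1_500.0, 90_000.0))
            s.median_f0, s.f0_track = track.median, track.f0
        except ba.NoVoicedFramesError:
            pass
        syllables.append(s)
    voiced = [s for s in syllables if s.median_f0 is not None]
    print(f"F0 tracked for {len(voiced)}/{len(syllables)} syllables")

    bouts = ba.segment_bouts(syllables)
    rows = []
    for i, b in enumerate(bouts):
        keep = [s for s in b.syllables if s.median_f0 is not None]
        if not keep:
            continue
        med, sd, durs = ba.bout_summary(ba.Bout(keep))
        rows.append({"bout": i, "onset_s": b.onset, "n_syllables": len(b),
                     "median_f0_hz": med, "sd_f0_hz": sd,
                     "mean_syllable_duration_s": float(np.mean(durs))})
    bout_df = pd.DataFrame(rows)
    bout_df.to_csv(OUT / "bouts.csv", index=False)
    print(f"{len(bouts)} bouts; median bout F0 "
          f"{bout_df['median_f0_hz'].median() / 1000:.1f} kHz")

    regions = read_regions(
        str(files("urbanrat").joinpath("data/illustrative_regions.csv")))
    feat = ba.project_feature_space(
        [ba.Bout([s]) for s in voiced], regions)
    feat.to_csv(OUT / "feature_space.csv", index=False)
    frac_out = feat["outside_all"].mean()
    print(f"{100 * frac_out:.0f}% of syllables fall outside the illustrative "
          f"reference boxes (duration-frequency plane)")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, verts in regions.items():
        xs, ys = zip(*(list(verts) + [verts[0]]))
        ax.fill(xs, np.array(ys) / 1000, alpha=0.2, label=name)
    ax.scatter(feat["duration_s"], feat["frequency_hz"] / 1000, s=12, c="k")
    for f_khz in (22, 50):
        ax.axhline(f_khz, ls="--", lw=0.8, c="gray")
    ax.set_xlabel("syllable duration (s)")
    ax.set_ylabel("median F0 (kHz)")
    ax.set_xscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "feature_space.png", dpi=120)
    print(f"wrote {OUT/'feature_space.png'}")


if __name__ == "__main__":
    main()
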
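#!/usr/bin/env python
"""Stage 2: rupture-event detection and per-event WLC fits.

Reads the sticking-mode curves written by 01_simulate_pulling.py,
runs baseline correction -> event detection (250 nm minimum
tip-substrate distance) -> WLC fit -> instantaneous loading rate, and
writes the events table results/events.tsv. If enough events are found,
effective contour lengths are clustered into discrete loop sizes.
"""

import argparse
from pathlib import Path

from slidepull.curves import (analyse_curve, events_to_dataframe,
                              loop_length_clusters, read_force_curves)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--curves", type=Path,
                    default=Path("results/curves/sticking"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    curves = read_force_curves(args.curves)
    events = []
    for c in curves:
        events.extend(analyse_curve(c))
    df = events_to_dataframe(events)
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results / "events.tsv", sep="\t", index=False)
    print(f"{len(curves)} curves -> {len(events)} analysed events")
    if len(events) == 0:
        return
    print(f"rupture force: median {df['rupture_force_pN'].median():.1f} pN, "
          f"IQR {df['rupture_force_pN'].quantile(0.25):.1f}-"
          f"{df['rupture_force_pN'].quantile(0.75):.1f} pN")
    print(f"effective contour length: median {df['Lc_eff_nm'].median():.0f} nm")
    if len(events) >= 10:
        res = loop_length_clusters(events)
        flag = " (flagged: weak structure)" if res.flagged else ""
        print(f"loop-length clustering: k = {res.k}, "
              f"centers {[round(c) for c in res.centers]} nm, "
              f"silhouette {res.quality:.2f}{flag}")


if __name__ == "__main__":
    main()
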
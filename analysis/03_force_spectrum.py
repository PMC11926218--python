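#!/usr/bin/env python
"""Stage 3: dynamic force spectrum and Bell-Evans fit.

Draws a synthetic rupture-force sample with known (k_off, x_beta) from
the exact Bell first-passage distribution across three decades of
loading rate, fits the Bell-Evans model to binned means, and writes
results/bell_evans.json plus the binned spectrum
results/force_spectrum_bins.tsv.
"""

import argparse
import json
from pathlib import Path

from slidepull.curves import fit_bell_evans_points
from slidepull.synth import RuptureSamplePlan, make_rupture_sample


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--k-off", type=float, default=0.002)
    ap.add_argument("--x-beta", type=float, default=1.2)
    ap.add_argument("--n", type=int, default=500)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    plan = RuptureSamplePlan(k_off=args.k_off, x_beta=args.x_beta,
                             rate_min=1e2, rate_max=1e5, n=args.n,
                             seed=args.seed)
    df, truth = make_rupture_sample(plan)
    fit = fit_bell_evans_points(df["loading_rate_pN_s"].to_numpy(),
                                df["rupture_force_pN"].to_numpy())
    out = {
        "truth": truth,
        "fit": {
            "k_off_s": fit.k_off_zero_force,
            "k_off_stderr_s": fit.k_off_stderr,
            "x_beta_nm": fit.barrier_width,
            "x_beta_stderr_nm": fit.barrier_width_stderr,
            "n_events": fit.n_events,
            "converged": fit.converged,
        },
        "note": "fitting the most-probable-force model to bin means "
                "overestimates k_off by ~e^gamma (~1.78x); x_beta is unbiased",
    }
    args.results.mkdir(parents=True, exist_ok=True)
    (args.results / "bell_evans.json").write_text(json.dumps(out, indent=1))
    fit.bin_table.to_csv(args.results / "force_spectrum_bins.tsv",
                         sep="\t", index=False)
    print(f"truth: k_off = {truth['k_off_s']} /s, x_beta = {truth['x_beta_nm']} nm")
    print(f"fit:   k_off = {fit.k_off_zero_force:.3g} +/- {fit.k_off_stderr:.2g} /s, "
          f"x_beta = {fit.barrier_width:.3g} +/- {fit.barrier_width_stderr:.2g} nm "
          f"({fit.n_events} events, {len(fit.bin_table)} bins)")


if __name__ == "__main__":
    main()
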
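#!/usr/bin/env python
"""Stage 4: closed-form receptor-polysaccharide binding-rate estimates.

Evaluates the end-on association-rate lower bound, a side-on (loop)
association rate from an assumed binding probability per dwell, and the
implied dissociation constants; writes results/binding_rates.json.
"""

import argparse
import json
from pathlib import Path

from slidepull.kinetics import (EndOnGeometry, dissociation_constant,
                                end_concentration, end_on_kon_bound,
                                receptors_in_reach, side_on_kon)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rg", type=float, default=75.0,
                    help="polymer radius of gyration, nm")
    ap.add_argument("--drms", type=float, default=20.0,
                    help="rms receptor spacing, nm")
    ap.add_argument("--velocity", type=float, default=1.0,
                    help="tip approach velocity, um/s")
    ap.add_argument("--side-on-probability", type=float, default=0.3,
                    help="assumed side-on binding probability per dwell")
    ap.add_argument("--dwell", type=float, default=1.0,
                    help="surface dwell time, s")
    ap.add_argument("--k-off", type=float, default=0.002,
                    help="zero-force off rate for K_D, 1/s")
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    geom = EndOnGeometry(args.rg, args.drms, args.velocity)
    end_on = end_on_kon_bound(geom)
    c_end = end_concentration(args.rg)
    side = side_on_kon(args.side_on_probability, c_end, args.dwell)
    out = {
        "geometry": {
            "radius_of_gyration_nm": args.rg,
            "receptor_spacing_rms_nm": args.drms,
            "approach_velocity_um_s": args.velocity,
            "end_concentration_M": c_end,
            "receptors_in_reach": receptors_in_reach(args.rg, args.drms),
        },
        "end_on_kon_lower_bound_M_s": end_on.value,
        "side_on_kon_M_s": side.value,
        "side_on_inputs": {"P": args.side_on_probability,
                           "dwell_s": args.dwell},
        "K_D_end_on_M": dissociation_constant(args.k_off, end_on.value).value,
        "k_off_s": args.k_off,
    }
    args.results.mkdir(parents=True, exist_ok=True)
    (args.results / "binding_rates.json").write_text(json.dumps(out, indent=1))
    print(f"end-on k_on lower bound: {end_on.value:.3g} M^-1 s^-1")
    print(f"side-on k_on (P = {args.side_on_probability}, "
          f"t = {args.dwell} s): {side.value:.3g} M^-1 s^-1")
    print(f"K_D (end-on bound, k_off = {args.k_off} /s): "
          f"{out['K_D_end_on_M']:.3g} M")


if __name__ == "__main__":
    main()
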
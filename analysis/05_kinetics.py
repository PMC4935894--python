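#!/usr/bin/env python
"""Dissociation kinetics of the GRE constructs from simulated
single-molecule dwell times.

For each construct (GRE, smGRE, mmGRE) a censored exponential dwell-time
sample is drawn at the study-condition rates (0.30, 0.10, 0.20 1/s),
k_off is recovered by the censored MLE, k_on = k_off / K_D is derived
from the construct's equilibrium constant (30, 10, 20 nM), and the fold
decrease of k_off relative to unmethylated GRE is reported with
propagated uncertainty.  Expected pattern: ~3-fold stabilisation for the
side-methylated element, ~1.5-fold for the middle-methylated one, and
k_on unchanged (~1e7 1/(M s)) by methylation.

Output: results/kinetics.tsv.
"""

import argparse
from pathlib import Path

from basestack import kinetics as kin
from basestack import structure_io as sio
from basestack import synthetic_data as syn

RESULTS = Path("results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=5000)
    parser.add_argument("--window", type=float, default=60.0,
                        help="observation window, s")
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    rows = []
    fits = {}
    for i, (name, koff_true) in enumerate(syn.KOFF_DEFAULTS.items()):
        d = syn.simulate_dwell_times(koff_true, args.n, window=args.window,
                                     seed=args.seed + 11 * i)
        res = kin.analyse(d, k_d=syn.KD_DEFAULTS[name],
                          k_d_se=0.1 * syn.KD_DEFAULTS[name])
        fits[name] = res.k_off
        rows.append({
            "element": name, "koff_true": koff_true,
            "koff_fit": res.k_off.value, "koff_se": res.k_off.se,
            "n_events": res.k_off.n_events,
            "n_censored": res.k_off.n_censored,
            "survival_r2": res.k_off.survival_r2,
            "kd_m": res.k_d[0], "kon_fit": res.k_on[0], "kon_se": res.k_on[1],
        })
        print(f"{name}: k_off {res.k_off.value:.4f} +/- {res.k_off.se:.4f} 1/s "
              f"(true {koff_true}), k_on {res.k_on[0]:.3g} 1/(M s)")
    for name in ("smGRE", "mmGRE"):
        ratio, se = kin.fold_change(fits["GRE"].value, fits["GRE"].se,
                                    fits[name].value, fits[name].se)
        print(f"k_off fold decrease GRE -> {name}: {ratio:.2f} +/- {se:.2f}")
        rows.append({"element": f"fold_{name}", "koff_true": "",
                     "koff_fit": ratio, "koff_se": se, "n_events": "",
                     "n_censored": "", "survival_r2": "", "kd_m": "",
                     "kon_fit": "", "kon_se": ""})
    sio.write_report(rows, RESULTS / "kinetics.tsv")
    print(f"-> {RESULTS / 'kinetics.tsv'}")


if __name__ == "__main__":
    main()
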
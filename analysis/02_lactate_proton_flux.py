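"""Quantify lactate-induced proton flux with and without a proton antenna.

Emulates the oocyte co-expression experiment: cells expressing the
lactate/H+ cotransporter alone versus cells whose transport is
facilitated by a cytosolic carbonic-anhydrase proton antenna (modelled
as a 1.9-fold higher maximal flux, i.e. a 90% facilitation in the middle
of the reported 80–100% range).  Each simulated cell receives 3 and
10 mM lactate pulses followed by a terminal CO2/HCO3- pulse; the
analysis extracts the maximal rate of pH change during application and
withdrawal, the intrinsic buffer capacity from the CO2 pulse, and the
proton flux J_H, then compares conditions.

Writes ``results/lactate_flux.csv`` (per cell and event) and prints the
condition means and the measured facilitation.
"""

import argparse
from pathlib import Path

import pandas as pd

from protonflux import (
    ApplicationProtocol,
    SolutionSpec,
    buffer_capacity,
    extract_rate,
    gen_lactate_experiment,
    proton_flux,
)
from protonflux.trace_model import SolutionEvent

PROTOCOL = ApplicationProtocol((
    SolutionEvent("lactate", 3.0, 120.0, 300.0),
    SolutionEvent("lactate", 10.0, 480.0, 660.0),
    SolutionEvent("CO2", 5.0, 960.0, 1260.0),
))
CONDITIONS = {"MCT1": 4.0, "MCT1+CAII": 4.0 * 1.9}  # J_max, mM/min


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cells", type=int, default=24)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    solution = SolutionSpec()
    rows = []
    for cond, j_max in CONDITIONS.items():
        for cell in range(args.cells):
            seed = args.seed * 10_000 + cell + (0 if cond == "MCT1" else 5000)
            trace, gt = gen_lactate_experiment(
                PROTOCOL, J_max=j_max, K_m=5.0, beta_true=20.0,
                tau_s=60.0, noise_sd=0.005, dt_s=0.5, seed=seed,
            )
            buf = buffer_capacity(trace.crop(900.0, 1260.0), solution,
                                  pulse_start_s=960.0)
            for idx, ev in enumerate(PROTOCOL.events[:2]):
                for direction, (a, b) in {
                    "application": (ev.t_start, ev.t_start + 60.0),
                    "withdrawal": (ev.t_end, ev.t_end + 60.0),
                }.items():
                    rate = extract_rate(trace.crop(a, b), mode="max-slope",
                                        window_s=30.0, direction=direction)
                    flux = proton_flux(rate, buf)
                    rows.append({
                        "condition": cond, "cell": cell,
                        "lactate_mM": ev.concentration,
                        "direction": direction,
                        "dpH_dt_per_min": rate.slope,
                        "beta_i_mM_per_pH": buf.beta_i,
                        "J_H_mM_per_min": flux.J_H,
                        "J_true_mM_per_min":
                            gt.params["J_true_mM_per_min"][idx],
                    })
    df = pd.DataFrame(rows)
    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "lactate_flux.csv"
    df.to_csv(out, index=False)

    summary = (df.groupby(["condition", "lactate_mM", "direction"])
               ["J_H_mM_per_min"].agg(["mean", "sem"]))
    print(summary.round(3))
    for lac in (3.0, 10.0):
        base = df.query("condition=='MCT1' and lactate_mM==@lac and "
                        "direction=='application'")["J_H_mM_per_min"].mean()
        enh = df.query("condition=='MCT1+CAII' and lactate_mM==@lac and "
                       "direction=='application'")["J_H_mM_per_min"].mean()
        print(f"{lac:4.0f} mM lactate: proton-antenna facilitation "
              f"{100 * (enh / base - 1):.0f}% (generated: 90%)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
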
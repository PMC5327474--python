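"""Generate every synthetic input for the downstream analyses.

Writes, under ``results/run/``: two cohorts of one-hour vessel traces
("ko"-like active cohort and a quieter "wt"-like cohort), per-animal
seizure/vasospasm event trains with short-lag coupling, and a
multi-channel 3D volume with a calibrated marker distance shift and one
focal stricture.  All seeds are fixed here, so every later script is
reproducible end to end.
"""

import dataclasses
import json
from pathlib import Path

from vasodyn import io, synthio

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # --- traces: two cohorts, 4 animals x 10 vessels each ------------------
    traces, truth = [], {}
    for cohort, rate, magnitude, base_seed in (
            ("ko", 0.456, 4.27, 100), ("wt", 0.076, 4.27, 200)):
        for a in range(4):
            params = synthio.TraceGenParams(
                n_vessels=10, spasm_rate=rate, magnitude=magnitude,
                plateau=139.66, noise_sd=0.005, seed=base_seed + a)
            tr, gt = synthio.gen_vessel_traces(
                params, animal_id=f"{cohort}-a{a}", cohort=cohort)
            traces += tr
            truth.update(gt)
    io.write_traces(traces, OUT / "traces.csv")
    (OUT / "traces_truth.json").write_text(json.dumps(
        {vid: [dataclasses.asdict(e) for e in evs]
         for vid, evs in truth.items()}, indent=1))
    print(f"traces: {len(traces)} vessels, "
          f"{sum(len(v) for v in truth.values())} true events")

    # --- event trains -------------------------------------------------------
    params = synthio.TrainGenParams(n_animals=8, session=10.0,
                                    seizure_rate=2.0,
                                    background_spasm_rate=0.5,
                                    coupling_fraction=0.5, lag_mean=40.0,
                                    lag_sd=20.0, seed=300)
    trains, train_truth = synthio.gen_event_trains(params)
    io.write_trains(trains, OUT / "trains.csv")
    n_cpl = sum(int(g["coupled"].sum()) for g in train_truth.values())
    print(f"trains: {len(trains)} animals, {n_cpl} coupled spasms")

    # --- volume -------------------------------------------------------------
    params = synthio.StackGenParams(
        shape=(24, 256, 256), voxel_size=(2.0, 0.5, 0.5), n_vessels=6,
        vessel_radius=2.0, n_cells=300, positive_fraction=0.5,
        target_shift=15.17, stricture_spec=((0, 40.0, 1.0),),
        vessel_intensity=200.0, noise_sd=10.0, seed=400)
    stack, stack_truth = synthio.gen_stack(params)
    io.write_stack(stack, OUT)
    import pandas as pd

    c = stack_truth["centroids_um"]
    io.write_cells(pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(len(c))],
        "z_um": c[:, 0], "y_um": c[:, 1], "x_um": c[:, 2],
        "marker_pos": stack_truth["positive"].astype(int),
    }), OUT / "cells.csv")
    (OUT / "stack_truth.json").write_text(json.dumps({
        "realized_shift_percent": stack_truth["realized_shift_percent"],
        "total_cells": stack_truth["total_cells"],
        "strictures": stack_truth["strictures"],
    }, indent=1))
    print(f"stack: realized shift "
          f"{stack_truth['realized_shift_percent']:.2f}% "
          f"(target {params.target_shift}%)")


if __name__ == "__main__":
    main()
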
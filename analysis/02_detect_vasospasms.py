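"""Detect vasospasms in the simulated cohorts and summarize per cohort.

Reads ``results/run/traces.csv`` (written by 01), runs the ΔF/F +
iterative masked-baseline detector on every vessel, and writes:

* ``results/run/events.csv`` — one row per detected event,
* ``results/run/vessel_metrics.csv`` — per-vessel rate/likelihood/means,
* ``results/tables/cohort_summary.csv`` — cohort means ± s.e.m. with
  two-sample comparisons (vessel-level for rate/likelihood/magnitude,
  animal-level for the fraction of vessels with ≥1 spasm).
"""

from pathlib import Path

import pandas as pd

from vasodyn import io, vasodynamics as vd

RUN = Path(__file__).resolve().parent.parent / "results" / "run"
TABLES = RUN.parent / "tables"


def main():
    traces = io.read_traces(RUN / "traces.csv")
    events = {tr.vessel_id: vd.analyze_trace(tr) for tr in traces}
    io.write_events(events, RUN / "events.csv")
    metrics = [vd.vessel_metrics(events[tr.vessel_id], tr) for tr in traces]
    vd.metrics_frame(metrics).to_csv(RUN / "vessel_metrics.csv", index=False)

    summary = vd.cohort_summary(metrics)
    rows = []
    for cohort, measures in summary.summaries.items():
        for measure, s in measures.items():
            rows.append({"cohort": cohort, "measure": measure, **s})
    for cohort, f in summary.fraction_of_vessels.items():
        rows.append({"cohort": cohort, "measure": "fraction_of_vessels",
                     "mean": f["mean"], "sem": f["sem"],
                     "n": len(f["per_animal"])})
    table = pd.DataFrame(rows)
    cmp_rows = [{"measure": m, "unit": summary.units[m], "t": r.statistic,
                 "df": r.df, "p": r.p, "method": r.method}
                for m, r in summary.comparisons.items()]
    TABLES.mkdir(parents=True, exist_ok=True)
    table.to_csv(TABLES / "cohort_summary.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(TABLES / "cohort_comparisons.csv",
                                  index=False)

    n_ev = sum(len(v) for v in events.values())
    print(f"{n_ev} events across {len(traces)} vessels")
    for _, r in pd.DataFrame(cmp_rows).iterrows():
        print(f"  {r['measure']:>24s} ({r['unit']}): "
              f"t={r['t']:.2f}, df={r['df']:.0f}, p={r['p']:.4g}")


if __name__ == "__main__":
    main()
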
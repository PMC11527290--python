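"""Precompute the reduced infant-region simulation library.

Simulates every combination of the 72-entry desk-scale grid (the full
published grid has ~4.7e5 combinations and is only needed for real
multi-month records) and reports how many entries survive the two
feasibility filters used during fitting: average bouts per day >= 1.5 and
an observed pacemaker period within [23.995, 24.005] h.

Writes results/reduced_library.csv (+ manifest), which scripts 03 and 04
reuse; the build is resumable, so re-running is cheap.
"""

import os

from sleepswitch.fitting import DEFAULT_MIN_BPD, DEFAULT_PERIOD_BAND
from sleepswitch.pipelines import build_reduced_library

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
LIBRARY_PATH = os.path.join(OUT, "reduced_library.csv")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    lib = build_reduced_library(cache_path=LIBRARY_PATH, progress=True)
    t = lib.table
    ok = t.sim_ok.sum()
    bpd_ok = (t.sim_ok & (t.bpd >= DEFAULT_MIN_BPD)).sum()
    feas = (t.sim_ok & (t.bpd >= DEFAULT_MIN_BPD)
            & t.tau_obs.between(*DEFAULT_PERIOD_BAND)).sum()
    print(f"{len(lib)} combinations simulated; {ok} solver-ok; "
          f"{bpd_ok} with BPD >= {DEFAULT_MIN_BPD}; "
          f"{feas} also inside the period band {DEFAULT_PERIOD_BAND}")
    print(f"BPD range {t.bpd.min():.2f}-{t.bpd.max():.2f}, "
          f"profile TSD range "
          f"{(t.filter(like='prob_').sum(axis=1) * 0.5).min():.1f}-"
          f"{(t.filter(like='prob_').sum(axis=1) * 0.5).max():.1f} h")
    print(f"library at {LIBRARY_PATH}")


if __name__ == "__main__":
    main()
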
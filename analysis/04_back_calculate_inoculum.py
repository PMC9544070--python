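#!/usr/bin/env python
"""Invert the model: which inoculum explains a given harvest?

Reproduces the troubleshooting use-case of the QC logs: a conspicuously
low harvest is traced back, via monotone bisection on the initial adult
count, to the inoculum size that would have produced it.  Also reports the
model-derived inoculum window that keeps plants healthy while clearing a
yield floor.
"""

import whiteflysim as w
from whiteflysim.planning import back_calculate_inoculum, recommend_inoculum


def main() -> None:
    params = w.default_parameters()
    standard = w.simulate(w.inoculation_state(), params, 7)
    print(f"standard harvest: {standard.final.T:.0f} adults from 100 inoculated")

    # a run that harvested only a quarter of the usual yield
    low_harvest = standard.final.T / 4.0
    point, (lo, hi) = back_calculate_inoculum(low_harvest, params)
    print(f"harvest of {low_harvest:.0f} back-calculates to an inoculum of "
          f"{point:.0f} adults (band {lo:.0f}-{hi:.0f} for +/-25% harvest "
          "uncertainty) -- an under-inoculation, not a sick colony")

    interval, diag = recommend_inoculum(
        params, min_final_area_fold=3.0, yield_floor=5000.0
    )
    print(f"model-recommended inoculum window for >=5000 adults and >=3-fold "
          f"final plant area: {interval[0]:.0f}-{interval[1]:.0f} adults")
    print("  (the empirical practice of 80-110 adults sits inside it)")


if __name__ == "__main__":
    main()
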
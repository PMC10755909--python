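#!/usr/bin/env python
"""Regenerate the scenario tables from the bundled parameter reconstruction.

Builds the 70-cell (c, d, b) table, predicts net assimilation for the
200/400/850-ppm CO2 scenarios, derives percent increments against the
solar-spectrum reference cell (37R36G27B at 350 umol m-2 s-1, 400 ppm) and
light-use efficiency, and writes everything under results/.
"""

from pathlib import Path

import co2resp as cr
from co2resp.curve_model import params_frame
from co2resp.io import write_grid_csv, write_params_csv
from co2resp.scenario_metrics import relative_increment_table
from co2resp.util import round_half_up

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    effects = cr.load_reference_effects()
    write_params_csv(params_frame(effects), OUT / "params_cells.csv")

    grid = cr.scenario_table(effects)
    write_grid_csv(grid.values.rename(columns={"an": "value"}),
                   OUT / "an_grid.csv", "value", decimals=2)
    rel = relative_increment_table(effects)
    write_grid_csv(rel.rename(columns={"relative": "value"}),
                   OUT / "relative_grid.csv", "value", decimals=0)
    cells, means = cr.plue_table(effects)
    write_grid_csv(cells.rename(columns={"plue": "value"}),
                   OUT / "plue_grid.csv", "value", decimals=2)
    means.to_csv(OUT / "plue_means.csv", index=False)

    ref = grid.cell("37R36G27B", 350.0, 400.0)
    best = grid.cell("20R80B", 200.0, 400.0)
    print(f"solar reference cell (350 PPFD, 400 ppm): An = {round_half_up(ref, 2)}")
    print(f"best mix 20R80B at 200 PPFD, 400 ppm:     An = {round_half_up(best, 2)} "
          f"({round_half_up(cr.relative_increment(best, ref), 0):.0f}% above reference "
          f"with 150 umol m-2 s-1 less light)")
    print(f"its light-use efficiency: "
          f"{round_half_up(cr.plue(best, 200.0).plue, 2)} mmol CO2/mol photons "
          f"(at 850 ppm: {round_half_up(cr.plue(grid.cell('20R80B', 200.0, 850.0), 200.0).plue, 2)})")
    m = means.set_index(["intensity", "co2"]).plue
    print(f"mean PLUE over the ten spectra at 200 PPFD, 400 ppm: "
          f"{round_half_up(float(m.loc[(200.0, 400.0)]), 2)}")
    print(f"wrote grids to {OUT}")


if __name__ == "__main__":
    main()
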
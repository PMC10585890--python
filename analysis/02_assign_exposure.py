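#!/usr/bin/env python
"""Assign tract-level exposure means from the pollutant rasters.

Reads the ESRI ASCII grids and tract polygons written by
01_simulate_city.py and computes, for every tract, the exact
area-weighted mean of all overlapping grid cells.
"""

from pathlib import Path

from portmort.exposure import assign_exposures
from portmort.io import read_grid, read_tracts, write_exposures

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    tracts = read_tracts(OUT / "tracts.geojson")
    grids = {}
    for asc in sorted(OUT.glob("exposure_*.asc")):
        name = asc.stem.removeprefix("exposure_")
        grids[name] = read_grid(asc, pollutant=name)
    exposures = assign_exposures(grids, tracts)
    write_exposures(exposures, OUT / "exposures.csv")
    summary = exposures.groupby("pollutant")["mean"].describe()
    print("tract exposure means (ug/m3):")
    print(summary[["mean", "std", "min", "max"]].round(2).to_string())
    print(f"wrote {OUT / 'exposures.csv'}")


if __name__ == "__main__":
    main()
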
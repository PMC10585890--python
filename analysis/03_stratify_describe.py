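#!/usr/bin/env python
"""Harbour stratification and the descriptive population table.

Classifies tracts by centroid distance to the harbour (800 m buffer,
with 600/1000 m sensitivity strata) and writes the population /
exposure / mortality summary by stratum.
"""

from pathlib import Path

from portmort.io import (
    read_config,
    read_deaths,
    read_exposures,
    read_tracts,
    write_stratum,
    _atomic_write,
)
from portmort.stratify import (
    classify_harbour,
    descriptive_table,
    format_descriptive_table,
    sensitivity_radii,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    cfg = read_config(OUT / "config_resolved.yaml")
    tracts = read_tracts(OUT / "tracts.geojson")
    deaths = read_deaths(OUT / "deaths.csv")
    exposures = read_exposures(OUT / "exposures.csv")

    stratum = classify_harbour(tracts, cfg.harbour_centroid,
                               cfg.harbour_radius_m)
    write_stratum(stratum, OUT / "stratum.csv")

    sens = sensitivity_radii(tracts, cfg.harbour_centroid,
                             [600.0, 800.0, 1000.0])
    _atomic_write(OUT / "sensitivity_buffers.csv",
                  sens.to_csv(index=False, float_format="%.10g"))
    print("harbour stratum by buffer radius:")
    print(sens.round({"pop_share": 4}).to_string(index=False))

    descriptives = descriptive_table(tracts, deaths, exposures, stratum)
    _atomic_write(OUT / "descriptives.csv",
                  descriptives.to_csv(index=False, float_format="%.10g"))
    text = format_descriptive_table(descriptives)
    _atomic_write(OUT / "descriptives.txt", text)
    print()
    print(text)


if __name__ == "__main__":
    main()
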
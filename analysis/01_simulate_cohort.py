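#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the study layout — 5 IDC and 5 ILC patients, one tumor and one
NAT sample each — with 10% of proteins planted at fold change 3, two
planted kinase activity shifts (AKT1 up, MAPK3 down, IDC tumors only) and
intensity-dependent dropout.  Writes the bundle that the downstream
analysis scripts read.
"""

from pathlib import Path

from phosphopair import SimulationParams, write_fixture_bundle

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
PARAMS = SimulationParams(
    seed=20230331,
    n_proteins=1000,
    n_sites=2000,
    planted_kinases={"AKT1": 1.2, "MAPK3": -1.0},
)


def main() -> None:
    files = write_fixture_bundle(OUTDIR, PARAMS)
    n_diff = round(PARAMS.frac_differential * PARAMS.n_proteins)
    print(f"wrote {len(files)} files to {OUTDIR}")
    print(f"planted: {n_diff} differential proteins at FC {PARAMS.planted_fc}, "
          f"kinases {PARAMS.planted_kinases} in {PARAMS.planted_subtype} tumors, "
          f"missing rate {PARAMS.missing_rate} (MNAR)")


if __name__ == "__main__":
    main()
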
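#!/usr/bin/env python
"""Kinase-activity inference on the synthetic cohort.

Feeds the per-subtype site-level fold changes into KSEA, annotates kinome
groups and compares the two subtypes' kinase sets.
"""

import json
from pathlib import Path

import pandas as pd

from phosphopair import read_design, read_kinase_substrates, read_phospho_table
from phosphopair.ksea import (
    annotate_kinome_group,
    compare_subtype_kinomes,
    ksea_scores,
    significant_kinases,
    site_fc_map_from_screen,
)
from phosphopair.normalization import global_normalize, to_log2
from phosphopair.paired_differential import differential_screen, patient_coverage_filter
from phosphopair.phospho_processing import filter_sites, site_gene_map, site_matrix
from phosphopair.tables_io import load_kinome_groups

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = BASE / "cohort"
    design = read_design(cohort / "design.tsv")
    filtered = filter_sites(read_phospho_table(cohort / "phospho_sites.tsv", design))
    annotations = read_kinase_substrates(cohort / "kinase_substrates.tsv")
    groups = load_kinome_groups()

    S, _ = global_normalize(to_log2(site_matrix(filtered)))
    Sf = patient_coverage_filter(S, design)
    gene_map = site_gene_map(filtered)

    results = {}
    for subtype in ("IDC", "ILC"):
        screen = differential_screen(Sf, design, subtype)
        fc_map = site_fc_map_from_screen(screen, gene_map)
        res = annotate_kinome_group(ksea_scores(fc_map, annotations), groups)
        res.to_csv(BASE / f"ksea_{subtype}.tsv", sep="\t", index=False)
        results[subtype] = res
        sig = significant_kinases(res)
        print(f"{subtype}: {len(res)} kinases scored over {len(fc_map)} sites; "
              f"significant: "
              + (", ".join(f"{r.kinase} ({r.direction}, z={r.z:+.2f}, {r.kinome_group})"
                           for r in sig.itertuples()) or "none"))

    n_idc, n_ilc, n_common, flips = compare_subtype_kinomes(results["IDC"], results["ILC"])
    (BASE / "kinome_comparison.json").write_text(json.dumps(
        {"idc_only": n_idc, "ilc_only": n_ilc, "common": n_common,
         "direction_flips": list(flips["kinase"])}, indent=1))
    print(f"kinase sets: {n_common} common, {n_idc} IDC-only, {n_ilc} ILC-only; "
          f"direction flips: {list(flips['kinase'])}")


if __name__ == "__main__":
    main()
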
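#!/usr/bin/env python
"""Phosphosite filtering, site-level screen and protein-level aggregation.

Keeps class-I sites (localization probability > 0.75), treats each
(site, multiplicity) as its own feature, screens per subtype and collapses
site fold changes to one phosphorylation fold change per protein.
"""

from pathlib import Path

from phosphopair import read_design, read_phospho_table
from phosphopair.normalization import global_normalize, to_log2
from phosphopair.paired_differential import differential_screen, patient_coverage_filter
from phosphopair.phospho_processing import (
    aggregate_protein_phospho_fc,
    differential_phosphoproteins,
    filter_sites,
    multiplicity_summary,
    site_matrix,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = BASE / "cohort"
    design = read_design(cohort / "design.tsv")
    T = read_phospho_table(cohort / "phospho_sites.tsv", design)
    filtered = filter_sites(T)
    print(f"{len(T)} site rows read, {len(filtered)} are class I and unflagged")

    summary = multiplicity_summary(filtered, design)
    summary.to_csv(BASE / "multiplicity_summary.tsv", sep="\t")
    print(summary)

    S, _ = global_normalize(to_log2(site_matrix(filtered)))
    Sf = patient_coverage_filter(S, design)
    for subtype in ("IDC", "ILC"):
        d = differential_screen(Sf, design, subtype)
        d.to_csv(BASE / f"site_screen_{subtype}.tsv", sep="\t", index_label="feature_id")
        agg = aggregate_protein_phospho_fc(d)
        agg.to_csv(BASE / f"phospho_protein_fc_{subtype}.tsv", sep="\t")
        diff = differential_phosphoproteins(d)
        print(f"{subtype}: {len(agg)} phosphoproteins quantified, "
              f"{len(diff)} differential (>=1 called site)")


if __name__ == "__main__":
    main()
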
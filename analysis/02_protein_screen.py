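#!/usr/bin/env python
"""Differential protein screen on the synthetic cohort.

Normalizes, applies the >60% patient-coverage prefilter, runs the
three-criterion screen per subtype and scores the calls against the
planted ground truth.
"""

from pathlib import Path

from phosphopair import GroundTruth, read_design, read_protein_table
from phosphopair.normalization import global_normalize, to_log2
from phosphopair.paired_differential import differential_screen, patient_coverage_filter

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = BASE / "cohort"
    design = read_design(cohort / "design.tsv")
    X = read_protein_table(cohort / "protein_groups.tsv", design)
    truth = GroundTruth.from_json(cohort / "truth_protein.json")

    Xn, report = global_normalize(to_log2(X))
    Xf = patient_coverage_filter(Xn, design)
    print(f"{len(X.feature_ids)} proteins read, "
          f"{len(Xf.feature_ids)} pass the >60% pair-coverage filter")

    for subtype in ("IDC", "ILC"):
        d = differential_screen(Xf, design, subtype)
        d.to_csv(BASE / f"protein_screen_{subtype}.tsv", sep="\t", index_label="feature_id")
        planted = {f: v[subtype] for f, v in truth.feature_log2fc.items() if v[subtype] != 0}
        tp = sum(1 for f, s in planted.items()
                 if f in d.index and d.at[f, "call"] == ("up" if s > 0 else "down"))
        called = d.index[d["call"] != "ns"]
        print(f"{subtype}: {int((d['call'] == 'up').sum())} up, "
              f"{int((d['call'] == 'down').sum())} down; "
              f"recalled {tp}/{len(planted)} planted proteins "
              f"({len(called)} total calls)")


if __name__ == "__main__":
    main()
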
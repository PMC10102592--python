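"""Seeded validation experiments over the synthetic generator.

Each function runs one recovery or calibration study end to end through the
library and returns plain numbers; the acceptance script and the test suite
both call these, so the reported quantities are always recomputed from
scratch.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .ksea import KSEAConfig, ksea_scores
from .normalization import global_normalize, to_log2
from .paired_differential import ScreenConfig, differential_screen, patient_coverage_filter
from .synthetic_data import SimulationParams, simulate_protein_dataset, simulate_site_fc_map
from .tables_io import SUBTYPES


def protein_recovery_experiment(
    seeds: Sequence[int],
    n_proteins: int = 1000,
    cfg: ScreenConfig = ScreenConfig(),
) -> dict:
    """Planted-protein recall and false-discovery rate of the full screen.

    For each seed: simulate the default 5+5-pair cohort with 10% of
    proteins planted at fold change 3, run normalization, coverage filter
    and the per-subtype screen, and score calls against ground truth.  A
    true positive is a planted (feature, subtype) called in the planted
    direction; any other call is false.  Returns the medians over seeds.
    """
    recalls, fdrs, null_rates = [], [], []
    for seed in seeds:
        X, design, truth = simulate_protein_dataset(
            SimulationParams(seed=seed, n_proteins=n_proteins))
        Xn, _ = global_normalize(to_log2(X))
        Xf = patient_coverage_filter(Xn, design, cfg)
        calls = {}
        for subtype in SUBTYPES:
            d = differential_screen(Xf, design, subtype, cfg)
            for fid, call in d["call"].items():
                calls[(fid, subtype)] = call
        planted = {
            (f, s): v[s]
            for f, v in truth.feature_log2fc.items()
            for s in SUBTYPES
            if v[s] != 0.0
        }
        tp = sum(
            1 for key, shift in planted.items()
            if calls.get(key, "ns") == ("up" if shift > 0 else "down")
        )
        called = [key for key, c in calls.items() if c != "ns"]
        fp = sum(
            1 for key in called
            if key not in planted
            or calls[key] != ("up" if planted[key] > 0 else "down")
        )
        n_null = sum(1 for key in calls if key not in planted)
        null_called = sum(1 for key, c in calls.items() if key not in planted and c != "ns")
        recalls.append(tp / len(planted))
        fdrs.append(fp / max(1, len(called)))
        null_rates.append(null_called / n_null)
    return {
        "median_recall": float(np.median(recalls)),
        "median_fdr": float(np.median(fdrs)),
        "max_null_call_rate": float(np.max(null_rates)),
        "n_seeds": len(list(seeds)),
        "n_proteins": n_proteins,
    }


def ksea_top_rank_recovery(
    seeds: Iterable[int],
    shift: float = 1.0,
    n_sites: int = 2000,
    substrates: int = 20,
    background_sd: float = 0.5,
) -> dict:
    """Fraction of runs where the planted kinase ranks first by |z| with
    p < 0.05, against decoy kinases with random substrate sets."""
    seeds = list(seeds)
    hits = 0
    for seed in seeds:
        fc, ann = simulate_site_fc_map(
            seed, n_sites=n_sites, background_sd=background_sd,
            kinase_shifts={"PLANTED": shift}, substrates_per_kinase=substrates,
            n_null_kinases=10,
        )
        res = ksea_scores(fc, ann)
        top = res.loc[res["z"].abs().idxmax()]
        if top["kinase"] == "PLANTED" and top["p"] < 0.05:
            hits += 1
    return {"recovery_fraction": hits / len(seeds), "n_runs": len(seeds)}


def ksea_null_calibration(
    seeds: Iterable[int],
    n_sites: int = 2000,
    n_kinases: int = 50,
    background_sd: float = 0.5,
) -> dict:
    """Fraction of null kinases reaching p < 0.05 (should sit near 0.05)."""
    seeds = list(seeds)
    n_sig = n_total = 0
    for seed in seeds:
        fc, ann = simulate_site_fc_map(
            seed, n_sites=n_sites, background_sd=background_sd,
            n_null_kinases=n_kinases,
        )
        res = ksea_scores(fc, ann, KSEAConfig())
        n_sig += int((res["p"] < 0.05).sum())
        n_total += len(res)
    return {"fraction_significant": n_sig / n_total, "n_kinase_tests": n_total,
            "n_runs": len(seeds)}


def normalization_recovery(seed: int, n_features: int = 4000) -> dict:
    """Pearson r between recovered offsets and the negated planted
    per-sample log2 scale biases, on a no-signal cohort."""
    X, _, truth = simulate_protein_dataset(
        SimulationParams(seed=seed, n_proteins=n_features, frac_differential=0.0))
    _, report = global_normalize(to_log2(X))
    offsets = report.offsets.set_index("sample_id")["offset_log2"]
    planted = -np.array([truth.sample_offsets[s] for s in offsets.index])
    r = float(np.corrcoef(offsets.to_numpy(), planted)[0, 1])
    return {"pearson_r": r, "n_features": n_features}
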
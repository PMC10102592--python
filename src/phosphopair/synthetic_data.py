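"""Synthetic paired proteome/phosphoproteome cohorts with known ground truth.

The generator emulates the study design every stage expects: two histological
subtypes with five tumor/NAT patient pairs each, log-normal per-sample peak
areas, per-sample multiplicative scale biases, patient random effects shared
between a patient's tumor and NAT samples, planted differential features at a
stated fold change, planted kinase activations expressed as coherent log2
shifts on the kinase's annotated substrate sites, and intensity-dependent
(missing-not-at-random) dropout implemented as a logistic in the log2
intensity whose intercept is calibrated so the overall missing fraction hits
``missing_rate``.

All randomness flows from the single ``seed`` through one
``numpy.random.Generator``; identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .tables_io import (
    IntensityMatrix,
    KinaseSubstrateTable,
    PairedDesign,
    PhosphoSiteTable,
    SUBTYPES,
    load_toy_kinase_substrates,
    write_design,
    write_kinase_substrates,
    write_phospho_table,
    write_protein_table,
)


@dataclass(frozen=True)
class SimulationParams:
    seed: int
    n_pairs_per_subtype: int = 5
    n_proteins: int = 1000
    n_sites: int = 2000
    frac_differential: float = 0.1
    planted_fc: float = 3.0
    within_group_log2_sd: float = 0.5
    patient_log2_sd: float = 0.3
    sample_scale_log2_sd: float = 0.3
    missing_rate: float = 0.1
    mnar_strength: float = 1.0
    frac_low_localization: float = 0.1
    sites_per_protein: int = 4
    planted_kinases: dict[str, float] = field(default_factory=dict)
    planted_subtype: str = "IDC"
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("frac_differential", "missing_rate", "frac_low_localization"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate 1.0 leaves no data")
        if self.planted_fc <= 0:
            raise ValueError("planted_fc must be positive")
        if self.n_pairs_per_subtype < 2:
            raise ValueError("need at least 2 pairs per subtype")
        if self.planted_subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.planted_subtype!r}")


@dataclass
class GroundTruth:
    """Planted signal: per-feature log2 FC per subtype, per-sample log2
    scale offsets, per-kinase activity shifts."""

    feature_log2fc: dict[str, dict[str, float]]
    sample_offsets: dict[str, float]
    kinase_shifts: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_design(n_pairs_per_subtype: int = 5) -> PairedDesign:
    """P1..Pn IDC then ILC patients, samples <patient>_T / <patient>_N."""
    rows = []
    for i in range(2 * n_pairs_per_subtype):
        patient = f"P{i + 1}"
        subtype = "IDC" if i < n_pairs_per_subtype else "ILC"
        rows.append({"sample": f"{patient}_T", "patient": patient, "tissue": "tumor", "subtype": subtype})
        rows.append({"sample": f"{patient}_N", "patient": patient, "tissue": "NAT", "subtype": subtype})
    return PairedDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# shared generative core
# ---------------------------------------------------------------------------


def _calibrate_dropout(log2_values: np.ndarray, rate: float, slope: float) -> np.ndarray:
    """Per-cell dropout probabilities: logistic decreasing in intensity,
    intercept bisected so the mean probability equals ``rate``."""
    if rate == 0.0:
        return np.zeros_like(log2_values)
    z = (log2_values - log2_values.mean()) / max(log2_values.std(), 1e-12)
    lo, hi = -50.0, 50.0
    for _ in range(80):
        c = 0.5 * (lo + hi)
        if expit(c - slope * z).mean() < rate:
            lo = c
        else:
            hi = c
    return expit(0.5 * (lo + hi) - slope * z)


def _simulate_values(
    rng: np.random.Generator,
    feature_log2fc: pd.DataFrame,  # features x subtypes, tumor-only shift
    design: PairedDesign,
    params: SimulationParams,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Linear-scale features x samples grid with MNAR dropout applied."""
    n_feat = len(feature_log2fc)
    patients = design.patients()
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n_feat)
    patient_eff = {
        p: rng.normal(0.0, params.patient_log2_sd, n_feat) for p in patients
    }
    offsets = {
        sid: float(rng.normal(0.0, params.sample_scale_log2_sd))
        for sid in design.sample_ids
    }
    cols = {}
    for row in design.entries.itertuples():
        value = baseline + patient_eff[row.patient]
        if row.tissue == "tumor":
            value = value + feature_log2fc[row.subtype].to_numpy()
        value = value + rng.normal(0.0, params.within_group_log2_sd, n_feat)
        cols[row.sample] = value + offsets[row.sample]
    log2 = pd.DataFrame(cols, index=feature_log2fc.index)

    p_drop = _calibrate_dropout(log2.to_numpy(), params.missing_rate, params.mnar_strength)
    dropped = rng.random(log2.shape) < p_drop
    linear = (2.0 ** log2).mask(pd.DataFrame(dropped, index=log2.index, columns=log2.columns))
    return linear, offsets


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def simulate_protein_dataset(
    params: SimulationParams,
) -> tuple[IntensityMatrix, PairedDesign, GroundTruth]:
    """Paired protein cohort with ``frac_differential`` features planted at
    +/- log2(planted_fc) (same shift in both subtypes, random sign)."""
    rng = np.random.default_rng(params.seed)
    design = make_design(params.n_pairs_per_subtype)
    features = [f"PROT{i + 1:04d}" for i in range(params.n_proteins)]

    n_diff = int(round(params.frac_differential * params.n_proteins))
    chosen = rng.choice(params.n_proteins, size=n_diff, replace=False)
    shifts = np.zeros(params.n_proteins)
    shifts[chosen] = rng.choice([-1.0, 1.0], size=n_diff) * np.log2(params.planted_fc)
    fc = pd.DataFrame({"IDC": shifts, "ILC": shifts}, index=pd.Index(features, name="feature_id"))

    linear, offsets = _simulate_values(rng, fc, design, params)
    truth = GroundTruth(
        feature_log2fc={
            f: {"IDC": float(fc.at[f, "IDC"]), "ILC": float(fc.at[f, "ILC"])}
            for f in features
        },
        sample_offsets=offsets,
        kinase_shifts={},
    )
    return IntensityMatrix(linear, "linear"), design, truth


# ---------------------------------------------------------------------------
# phosphoproteome
# ---------------------------------------------------------------------------


_RESIDUE_PROBS = {"S": 0.86, "T": 0.12, "Y": 0.02}


def simulate_phospho_dataset(
    params: SimulationParams,
    annotations: KinaseSubstrateTable,
) -> tuple[PhosphoSiteTable, PairedDesign, GroundTruth]:
    """Paired phosphosite cohort.

    Every annotated substrate site of each planted kinase appears as one
    quantified site and receives the kinase's log2 shift in the tumor
    samples of ``planted_subtype``.  Background sites are spread over a
    pool of proteins (~``sites_per_protein`` sites each); a
    ``frac_differential`` fraction of those proteins gets a protein-level
    +/- log2(planted_fc) shift on all of its sites in both subtypes.  A
    ``frac_low_localization`` fraction of background sites draws its
    localization probability below the 0.75 class-I cutoff to exercise the
    filter; planted substrate sites stay class I so the planted signal is
    what the filter passes through.
    """
    rng = np.random.default_rng(params.seed)
    design = make_design(params.n_pairs_per_subtype)

    planted_rows: list[dict] = []
    kinase_shifts: dict[str, float] = {}
    seen_sites: set[tuple[str, int]] = set()
    for kinase, shift in sorted(params.planted_kinases.items()):
        subs = annotations.substrates_of(kinase)
        if not subs:
            raise ValueError(f"planted kinase {kinase!r} has no annotated substrates")
        kinase_shifts[kinase.upper()] = float(shift)
        for gene, site in sorted(subs):
            residue, position = site[0], int(site[1:])
            if (gene, position) in seen_sites:
                continue
            seen_sites.add((gene, position))
            planted_rows.append(
                {"gene": gene, "residue": residue, "position": position, "kinase_shift": float(shift)}
            )
    if len(planted_rows) >= params.n_sites:
        raise ValueError("n_sites too small for the planted kinase substrates")

    n_background = params.n_sites - len(planted_rows)
    pool = [f"GENE{i + 1:04d}" for i in range(max(1, n_background // params.sites_per_protein))]
    n_diff = int(round(params.frac_differential * len(pool)))
    diff_idx = rng.choice(len(pool), size=n_diff, replace=False)
    protein_shift = {pool[i]: s for i, s in zip(
        diff_idx, rng.choice([-1.0, 1.0], size=n_diff) * np.log2(params.planted_fc))}

    residues = list(_RESIDUE_PROBS)
    res_p = list(_RESIDUE_PROBS.values())
    background_rows: list[dict] = []
    while len(background_rows) < n_background:
        gene = pool[int(rng.integers(len(pool)))]
        position = int(rng.integers(1, 2000))
        if (gene, position) in seen_sites:
            continue
        seen_sites.add((gene, position))
        background_rows.append(
            {
                "gene": gene,
                "residue": residues[int(rng.choice(len(residues), p=res_p))],
                "position": position,
                "kinase_shift": 0.0,
            }
        )

    rows = planted_rows + background_rows
    n_sites = len(rows)
    multiplicity = rng.choice([1, 2, 3], size=n_sites, p=[0.6, 0.3, 0.1])
    low_loc = np.zeros(n_sites, dtype=bool)
    n_planted = len(planted_rows)
    low_loc[n_planted:] = rng.random(n_sites - n_planted) < params.frac_low_localization
    loc_prob = np.where(
        low_loc,
        rng.uniform(0.30, 0.75, n_sites),
        rng.uniform(0.76, 1.0, n_sites),
    )

    feature_ids = [
        f"{r['gene']}:{r['residue']}{r['position']}:{m}"
        for r, m in zip(rows, multiplicity)
    ]
    fc = pd.DataFrame(0.0, index=pd.Index(feature_ids, name="feature_id"), columns=list(SUBTYPES))
    for i, r in enumerate(rows):
        base = protein_shift.get(r["gene"], 0.0)
        for subtype in SUBTYPES:
            shift = base + (r["kinase_shift"] if subtype == params.planted_subtype else 0.0)
            fc.iloc[i, fc.columns.get_loc(subtype)] = shift

    linear, offsets = _simulate_values(rng, fc, design, params)

    sites = pd.DataFrame(
        {
            "protein_id": [r["gene"] for r in rows],
            "gene": [r["gene"] for r in rows],
            "residue": [r["residue"] for r in rows],
            "position": [r["position"] for r in rows],
            "localization_prob": loc_prob,
            "multiplicity": multiplicity,
            "reverse_flag": False,
            "contaminant_flag": False,
        }
    )
    table = PhosphoSiteTable(sites, linear.reset_index(drop=True))
    truth = GroundTruth(
        feature_log2fc={
            fid: {"IDC": float(fc.at[fid, "IDC"]), "ILC": float(fc.at[fid, "ILC"])}
            for fid in feature_ids
        },
        sample_offsets=offsets,
        kinase_shifts=kinase_shifts,
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# direct KSEA-level simulation
# ---------------------------------------------------------------------------


def simulate_site_fc_map(
    seed: int,
    n_sites: int = 2000,
    background_sd: float = 0.5,
    kinase_shifts: dict[str, float] | None = None,
    substrates_per_kinase: int = 20,
    n_null_kinases: int = 0,
    null_substrate_range: tuple[int, int] = (3, 10),
) -> tuple[dict[tuple[str, str], float], KinaseSubstrateTable]:
    """Site log2 FC map plus matching annotations, for kinase-level studies.

    Background sites draw N(0, background_sd); every substrate of a shifted
    kinase has the shift added.  ``n_null_kinases`` extra kinases get random
    substrate sets with no shift, for calibration runs.
    """
    rng = np.random.default_rng(seed)
    keys = [(f"GENE{i + 1:05d}", f"S{int(rng.integers(1, 1500))}") for i in range(n_sites)]
    values = rng.normal(0.0, background_sd, n_sites)

    triples = []
    for kinase, shift in sorted((kinase_shifts or {}).items()):
        idx = rng.choice(n_sites, size=substrates_per_kinase, replace=False)
        values[idx] += shift
        triples += [
            {"kinase": kinase.upper(), "substrate_protein": keys[i][0], "site": keys[i][1]}
            for i in idx
        ]
    for j in range(n_null_kinases):
        m = int(rng.integers(null_substrate_range[0], null_substrate_range[1] + 1))
        idx = rng.choice(n_sites, size=m, replace=False)
        triples += [
            {"kinase": f"NULLK{j + 1:03d}", "substrate_protein": keys[i][0], "site": keys[i][1]}
            for i in idx
        ]
    annotations = KinaseSubstrateTable(
        pd.DataFrame(triples, columns=["kinase", "substrate_protein", "site"]).drop_duplicates().reset_index(drop=True)
    )
    return {k: float(v) for k, v in zip(keys, values)}, annotations


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = (
    "design.tsv",
    "protein_groups.tsv",
    "phospho_sites.tsv",
    "kinase_substrates.tsv",
    "truth_protein.json",
    "truth_phospho.json",
)


def write_fixture_bundle(
    outdir: str | Path, params: SimulationParams | None = None
) -> list[Path]:
    """Write a small ready-made cohort in the exact dialects the readers
    consume: design, proteinGroups-style TSV, Phospho(STY)Sites-style TSV,
    kinase-substrate annotations and the two ground-truth JSONs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = SimulationParams(
            seed=20230331, n_proteins=120, n_sites=160,
            planted_kinases={"AKT1": 1.2, "MAPK3": -1.0},
        )
    annotations = load_toy_kinase_substrates()
    X, design, truth_prot = simulate_protein_dataset(params)
    T, _, truth_phos = simulate_phospho_dataset(params, annotations)

    write_design(design, outdir / "design.tsv")
    write_protein_table(X, outdir / "protein_groups.tsv")
    write_phospho_table(T, outdir / "phospho_sites.tsv")
    write_kinase_substrates(annotations, outdir / "kinase_substrates.tsv")
    truth_prot.to_json(outdir / "truth_protein.json")
    truth_phos.to_json(outdir / "truth_phospho.json")
    return [outdir / name for name in BUNDLE_FILES]
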
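"""End-to-end orchestration: read -> normalize -> screen -> integrate -> KSEA.

Every stage writes a plain TSV or JSON report into the output directory and
logs its row counts into a run manifest, so a rerun with the same config and
seed reproduces the bundle byte for byte and no stage can silently lose
rows.  Every printed screening threshold is a config default, never a
constant at a call site.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ksea import (
    KSEAConfig,
    annotate_kinome_group,
    compare_subtype_kinomes,
    group_tally,
    ksea_scores,
    significant_kinases,
    site_fc_map_from_screen,
)
from .normalization import global_normalize, to_log2
from .paired_differential import ScreenConfig, differential_screen, patient_coverage_filter
from .phospho_processing import (
    SiteFilterConfig,
    aggregate_protein_phospho_fc,
    differential_phosphoproteins,
    filter_sites,
    multiplicity_summary,
    site_gene_map,
    site_matrix,
)
from .subtype_integration import (
    discordance_groups,
    layer_state,
    opposite_direction_counts,
    overlap_diff_protein_phospho,
    table2_quadrants,
    table2_signatures,
)
from .tables_io import (
    SUBTYPES,
    load_kinome_groups,
    load_table2_fixture,
    read_design,
    read_kinase_substrates,
    read_phospho_table,
    read_protein_table,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    protein_table: str
    phospho_table: str
    design: str
    kinase_substrates: str
    outdir: str
    group_map: str | None = None  # bundled kinome groups when None
    seed: int = 0
    intensity_prefix: str = "Intensity"
    normalization_enabled: bool = True
    normalization_method: str = "median"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    site_filter: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    phospho_agg_method: str = "median"
    ksea: KSEAConfig = field(default_factory=KSEAConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        paths = raw.get("paths", {})
        kwargs = dict(
            protein_table=paths["protein_table"],
            phospho_table=paths["phospho_table"],
            design=paths["design"],
            kinase_substrates=paths["kinase_substrates"],
            outdir=paths["outdir"],
            group_map=paths.get("group_map"),
            seed=int(raw.get("seed", 0)),
        )
        norm = raw.get("normalization", {})
        kwargs["normalization_enabled"] = bool(norm.get("enabled", True))
        kwargs["normalization_method"] = norm.get("method", "median")
        kwargs["intensity_prefix"] = raw.get("intensity_prefix", "Intensity")
        if "screen" in raw:
            kwargs["screen"] = ScreenConfig(**raw["screen"])
        phospho = raw.get("phospho", {})
        if "min_localization_prob" in phospho or "drop_flags" in phospho:
            kwargs["site_filter"] = SiteFilterConfig(
                min_localization_prob=phospho.get("min_localization_prob", 0.75),
                drop_flags=phospho.get("drop_flags", True),
            )
        kwargs["phospho_agg_method"] = phospho.get("agg_method", "median")
        if "ksea" in raw:
            kwargs["ksea"] = KSEAConfig(**raw["ksea"])
        return cls(**kwargs)


def _log(stage: str, started: float, **counts) -> dict:
    info = {"stage": stage, **counts}
    elapsed = round(time.monotonic() - started, 3)
    print(f"[phosphopair] {info} ({elapsed}s)", file=sys.stderr)
    return info  # timers stay on stderr so reruns are byte-identical


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_all(cfg: RunConfig) -> dict:
    """Execute the whole analysis chain and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {
            "normalization": {"enabled": cfg.normalization_enabled, "method": cfg.normalization_method},
            "screen": vars(cfg.screen).copy(),
            "site_filter": vars(cfg.site_filter).copy(),
            "phospho_agg_method": cfg.phospho_agg_method,
            "ksea": vars(cfg.ksea).copy(),
        },
        "stages": [],
    }
    stages = manifest["stages"]

    def run_stage(name, fn):
        started = time.monotonic()
        try:
            result, counts = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError(name, exc) from exc
        stages.append(_log(name, started, **counts))
        return result

    # -- read ---------------------------------------------------------------
    design = run_stage("read_design", lambda: (
        (d := read_design(cfg.design)), {"n_samples": len(d.entries), "n_pairs": d.n_pairs}))
    X_prot = run_stage("read_protein_table", lambda: (
        (x := read_protein_table(cfg.protein_table, design, cfg.intensity_prefix)),
        {"n_proteins": len(x.feature_ids)}))
    T_sites = run_stage("read_phospho_table", lambda: (
        (t := read_phospho_table(cfg.phospho_table, design, cfg.intensity_prefix)),
        {"n_site_rows": len(t)}))
    annotations = run_stage("read_kinase_substrates", lambda: (
        (a := read_kinase_substrates(cfg.kinase_substrates)), {"n_triples": len(a)}))
    group_map = (
        load_kinome_groups()
        if cfg.group_map is None
        else {
            str(k).upper(): str(g)
            for k, g in pd.read_csv(cfg.group_map, sep="\t").itertuples(index=False)
        }
    )

    # -- protein layer ------------------------------------------------------
    def protein_stage():
        X = to_log2(X_prot)
        if cfg.normalization_enabled:
            X, report = global_normalize(X, cfg.normalization_method)
            report.offsets.to_csv(outdir / "normalization_protein.tsv", sep="\t", index=False)
        X = patient_coverage_filter(X, design, cfg.screen)
        return X, {"n_after_coverage": len(X.feature_ids)}

    X_log2 = run_stage("protein_normalize_filter", protein_stage)

    protein_screens = {}
    for subtype in SUBTYPES:
        protein_screens[subtype] = run_stage(f"protein_screen_{subtype}", lambda s=subtype: (
            (d := differential_screen(X_log2, design, s, cfg.screen)),
            {"n_features": len(d), "n_up": int((d['call'] == 'up').sum()),
             "n_down": int((d['call'] == 'down').sum())}))
        protein_screens[subtype].to_csv(
            outdir / f"protein_screen_{subtype}.tsv", sep="\t", index_label="feature_id")

    # -- phospho layer ------------------------------------------------------
    def phospho_stage():
        filtered = filter_sites(T_sites, cfg.site_filter)
        multiplicity_summary(filtered, design).to_csv(outdir / "multiplicity_summary.tsv", sep="\t")
        S = to_log2(site_matrix(filtered))
        if cfg.normalization_enabled:
            S, report = global_normalize(S, cfg.normalization_method)
            report.offsets.to_csv(outdir / "normalization_phospho.tsv", sep="\t", index=False)
        S = patient_coverage_filter(S, design, cfg.screen)
        return (filtered, S), {"n_sites_after_filter": len(filtered),
                               "n_sites_after_coverage": len(S.feature_ids)}

    filtered_sites, S_log2 = run_stage("phospho_filter_normalize", phospho_stage)
    gene_map = site_gene_map(filtered_sites)

    site_screens, phospho_fcs, diff_phospho = {}, {}, {}
    for subtype in SUBTYPES:
        site_screens[subtype] = run_stage(f"site_screen_{subtype}", lambda s=subtype: (
            (d := differential_screen(S_log2, design, s, cfg.screen)),
            {"n_sites": len(d), "n_up": int((d['call'] == 'up').sum()),
             "n_down": int((d['call'] == 'down').sum())}))
        site_screens[subtype].to_csv(
            outdir / f"site_screen_{subtype}.tsv", sep="\t", index_label="feature_id")
        phospho_fcs[subtype] = aggregate_protein_phospho_fc(
            site_screens[subtype], cfg.phospho_agg_method)
        phospho_fcs[subtype].to_csv(outdir / f"phospho_protein_fc_{subtype}.tsv", sep="\t")
        diff_phospho[subtype] = differential_phosphoproteins(site_screens[subtype])

    # -- integration --------------------------------------------------------
    def integration_stage():
        diff_prot = {
            s: set(protein_screens[s].index[protein_screens[s]["call"] != "ns"])
            for s in SUBTYPES
        }
        union_prot = diff_prot["IDC"] | diff_prot["ILC"]
        fcs = pd.DataFrame(
            {
                "fc_idc": protein_screens["IDC"]["mean_fc"],
                "fc_ilc": protein_screens["ILC"]["mean_fc"],
            }
        ).loc[sorted(union_prot)].dropna()
        from .subtype_integration import quadrant_table

        quad = quadrant_table(fcs, cfg.screen)
        quad.to_csv(outdir / "quadrants.tsv", sep="\t", index_label="feature_id")
        n_ud, n_du = opposite_direction_counts(fcs, cfg.screen)

        union_phos = diff_phospho["IDC"] | diff_phospho["ILC"]
        n_both, n_prot_only, n_phos_only = overlap_diff_protein_phospho(union_prot, union_phos)

        # dual-layer signatures for proteins differential at both layers
        sig_rows = []
        for protein in sorted(union_prot & union_phos):
            try:
                states = {
                    "prot_idc": layer_state(protein_screens["IDC"].at[protein, "mean_fc"], cfg.screen),
                    "prot_ilc": layer_state(protein_screens["ILC"].at[protein, "mean_fc"], cfg.screen),
                    "phos_idc": layer_state(phospho_fcs["IDC"].at[protein, "mean_fc"], cfg.screen),
                    "phos_ilc": layer_state(phospho_fcs["ILC"].at[protein, "mean_fc"], cfg.screen),
                }
            except (KeyError, ValueError):
                continue
            sig_rows.append({"feature_id": protein, **states})
        signatures = pd.DataFrame(
            sig_rows, columns=["feature_id", "prot_idc", "prot_ilc", "phos_idc", "phos_ilc"])
        signatures = signatures.set_index("feature_id")
        grouped = discordance_groups(signatures) if len(signatures) else signatures.assign(
            group=pd.Series(dtype=str), matches=pd.Series(dtype=str))
        grouped.to_csv(outdir / "signatures.tsv", sep="\t", index_label="feature_id")

        _write_json(
            {
                "idc_up_ilc_down": n_ud,
                "idc_down_ilc_up": n_du,
                "overlap_both_layers": n_both,
                "protein_only": n_prot_only,
                "phospho_only": n_phos_only,
            },
            outdir / "overlap.json",
        )
        return None, {"n_quadrant_rows": len(quad), "n_signatures": len(signatures)}

    run_stage("subtype_integration", integration_stage)

    # -- KSEA ---------------------------------------------------------------
    ksea_results = {}
    for subtype in SUBTYPES:
        def ksea_stage(s=subtype):
            fc_map = site_fc_map_from_screen(site_screens[s], gene_map)
            res = ksea_scores(fc_map, annotations, cfg.ksea)
            res = annotate_kinome_group(res, group_map)
            res.to_csv(outdir / f"ksea_{s}.tsv", sep="\t", index=False)
            sig = significant_kinases(res, cfg.ksea)
            sig.to_csv(outdir / f"ksea_significant_{s}.tsv", sep="\t", index=False)
            group_tally(res).rename("n_kinases").to_csv(outdir / f"ksea_groups_{s}.tsv", sep="\t")
            return res, {"n_kinases": len(res), "n_significant": len(sig), "n_sites_used": len(fc_map)}

        ksea_results[subtype] = run_stage(f"ksea_{subtype}", ksea_stage)

    def compare_stage():
        n_idc, n_ilc, n_common, direction = compare_subtype_kinomes(
            ksea_results["IDC"], ksea_results["ILC"])
        direction.to_csv(outdir / "kinase_direction_flips.tsv", sep="\t", index=False)
        _write_json(
            {"idc_only": n_idc, "ilc_only": n_ilc, "common": n_common,
             "n_direction_flips": len(direction)},
            outdir / "kinome_comparison.json",
        )
        return None, {"n_common_kinases": n_common}

    run_stage("compare_subtype_kinomes", compare_stage)

    _write_json(manifest, outdir / "manifest.json")
    return manifest


def table2_report() -> dict:
    """Quadrant, overlap and discordance-group summary computed from the
    bundled 13-row fixture of printed fold changes."""
    fixture = load_table2_fixture()
    quad = table2_quadrants(fixture)
    n_ud, n_du = opposite_direction_counts(
        quad[["fc_idc", "fc_ilc"]])
    dual = fixture.dual_layer()
    grouped = discordance_groups(table2_signatures(fixture))
    members = {
        g: sorted(grouped.index[grouped["group"] == g]) for g in ("G1", "G2", "G3")
    }
    return {
        "n_rows": int(len(fixture.rows)),
        "quadrant_counts": quad["quadrant"].value_counts().to_dict(),
        "idc_up_ilc_down": n_ud,
        "idc_down_ilc_up": n_du,
        "dual_layer_count": int(len(dual)),
        "groups": members,
        "unassigned": sorted(grouped.index[grouped["group"] == "unassigned"]),
    }
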
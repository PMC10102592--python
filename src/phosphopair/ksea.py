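"""Kinase-Substrate Enrichment Analysis (KSEA).

Kinase activity is inferred from the quantified phosphosites annotated as
its substrates: with s_bar the mean log2 fold change over the kinase's m
matched substrate sites, p_bar and delta the mean and sample (n-1 ddof)
standard deviation over *all* quantified sites, the kinase score is

    z = (s_bar - p_bar) * sqrt(m) / delta

with a two-tailed standard-normal p-value.  Positive z reads as activation
in tumor, negative as inactivation.  A kinase is reported as significant
when p < 0.05 and it has at least 3 matched substrates.  Each quantified
(protein, site) key contributes once per kinase even when the annotation
table maps the kinase to it through several rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import KinaseSubstrateTable


@dataclass(frozen=True)
class KSEAConfig:
    p_cutoff: float = 0.05
    min_substrates: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.min_substrates < 1:
            raise ValueError("min_substrates must be >= 1")


def ksea_scores(
    site_log2fc: Mapping[tuple[str, str], float],
    annotations: KinaseSubstrateTable,
    cfg: KSEAConfig = KSEAConfig(),
) -> pd.DataFrame:
    """Score every kinase with at least one quantified substrate site.

    ``site_log2fc`` maps (gene symbol, site string) — e.g. ("GSK3B", "S9")
    — to that site's log2 tumor/NAT fold change.  Returns a DataFrame sorted
    by z with columns kinase, m, mean_substrate_log2fc, global_mean_log2fc,
    global_sd_log2fc, z, p, direction, significant.
    """
    fc = {
        (str(g).upper(), str(s).upper()): float(v)
        for (g, s), v in site_log2fc.items()
        if np.isfinite(v)
    }
    if len(fc) < 2:
        raise ValueError("need at least 2 quantified sites")
    if len(annotations) == 0:
        raise ValueError("empty annotation table")
    background = np.fromiter(fc.values(), dtype=float)
    p_bar = float(background.mean())
    delta = float(background.std(ddof=1))
    if delta == 0.0:
        raise ValueError("degenerate background: all site fold changes identical")

    rows = []
    for kinase in annotations.kinases:
        hits = {key for key in annotations.substrates_of(kinase) if key in fc}
        if not hits:
            continue
        m = len(hits)
        s_bar = float(np.mean([fc[key] for key in hits]))
        z = (s_bar - p_bar) * math.sqrt(m) / delta
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "kinase": kinase,
                "m": m,
                "mean_substrate_log2fc": s_bar,
                "global_mean_log2fc": p_bar,
                "global_sd_log2fc": delta,
                "z": z,
                "p": p,
                "direction": "activated" if z > 0 else "inactivated",
                "significant": bool(p < cfg.p_cutoff and m >= cfg.min_substrates),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "kinase", "m", "mean_substrate_log2fc", "global_mean_log2fc",
            "global_sd_log2fc", "z", "p", "direction", "significant",
        ],
    )
    return out.sort_values("z", ascending=False, kind="mergesort").reset_index(drop=True)


def significant_kinases(results: pd.DataFrame, cfg: KSEAConfig = KSEAConfig()) -> pd.DataFrame:
    """p < cutoff AND m >= minimum substrate count."""
    keep = (results["p"] < cfg.p_cutoff) & (results["m"] >= cfg.min_substrates)
    return results[keep].reset_index(drop=True)


def annotate_kinome_group(results: pd.DataFrame, group_map: Mapping[str, str]) -> pd.DataFrame:
    """Label each kinase with its kinome group (or 'unknown')."""
    lut = {str(k).upper(): str(g) for k, g in group_map.items()}
    out = results.copy()
    out["kinome_group"] = [lut.get(k.upper(), "unknown") for k in out["kinase"]]
    return out


def group_tally(results: pd.DataFrame) -> pd.Series:
    """Kinase counts per kinome group (requires annotate_kinome_group)."""
    return results["kinome_group"].value_counts()


def compare_subtype_kinomes(
    results_idc: pd.DataFrame, results_ilc: pd.DataFrame
) -> tuple[int, int, int, pd.DataFrame]:
    """Set arithmetic on the two subtypes' kinase lists.

    Returns (n_idc_only, n_ilc_only, n_common, direction_table); the
    direction table lists kinases whose z signs disagree between subtypes.
    """
    idc = set(results_idc["kinase"])
    ilc = set(results_ilc["kinase"])
    common = idc & ilc
    zi = results_idc.set_index("kinase")["z"]
    zl = results_ilc.set_index("kinase")["z"]
    flipped = sorted(k for k in common if np.sign(zi[k]) != np.sign(zl[k]))
    direction = pd.DataFrame(
        {
            "kinase": flipped,
            "z_idc": [float(zi[k]) for k in flipped],
            "z_ilc": [float(zl[k]) for k in flipped],
        }
    )
    return len(idc - ilc), len(ilc - idc), len(common), direction


def site_fc_map_from_screen(
    site_diff: pd.DataFrame, gene_map: Mapping[str, tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Build the KSEA input map from a site-level screen table.

    Multiplicity classes of the same (gene, site) are averaged on the log2
    scale so each biological site contributes one value.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for fid, mean_fc in site_diff["mean_fc"].items():
        if not np.isfinite(mean_fc) or fid not in gene_map:
            continue
        key = gene_map[fid]
        acc.setdefault(key, []).append(math.log2(mean_fc))
    return {key: float(np.mean(vals)) for key, vals in acc.items()}
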
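"""Phosphosite filtering, multiplicity accounting and protein-level
aggregation.

Sites are kept when their localization probability strictly exceeds 0.75
(class I sites) and they carry no decoy/contaminant flag.  Each
(site, multiplicity) class is treated as a separate quantitative feature —
the same site quantified from singly and doubly phosphorylated peptides
reports two features — and the shared differential machinery runs on the
resulting site matrix.  Site-level fold changes are aggregated to one
phosphorylation fold change per protein as the median of site log2 fold
changes (mean available via ``agg_method``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import (
    IntensityMatrix,
    PairedDesign,
    PhosphoSiteTable,
    SUBTYPES,
    TISSUES,
)


@dataclass(frozen=True)
class SiteFilterConfig:
    min_localization_prob: float = 0.75  # strict ">"
    drop_flags: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_localization_prob <= 1:
            raise ValueError("min_localization_prob must be in [0, 1]")


def filter_sites(T: PhosphoSiteTable, cfg: SiteFilterConfig = SiteFilterConfig()) -> PhosphoSiteTable:
    """Localization-probability and flag filter (idempotent)."""
    mask = T.sites["localization_prob"] > cfg.min_localization_prob
    if cfg.drop_flags:
        mask &= ~T.sites["reverse_flag"] & ~T.sites["contaminant_flag"]
    return T.subset(mask)


def multiplicity_summary(T: PhosphoSiteTable, design: PairedDesign) -> pd.DataFrame:
    """Site counts per (subtype, tissue) stratum by multiplicity class.

    A site counts toward a stratum when any of its intensities is present
    in a sample of that stratum.  Columns: mult_1, mult_2, mult_3plus,
    total_sites, n_phosphoproteins.
    """
    rows = []
    for subtype in SUBTYPES:
        for tissue in TISSUES:
            samples = design.samples(subtype, tissue)
            if samples:
                observed = T.intensities[samples].notna().any(axis=1)
            else:
                observed = pd.Series(False, index=T.intensities.index)
            sub = T.sites[observed.to_numpy()] if len(T) else T.sites
            mult = sub["multiplicity"] if len(sub) else pd.Series(dtype=int)
            rows.append(
                {
                    "subtype": subtype,
                    "tissue": tissue,
                    "mult_1": int((mult == 1).sum()),
                    "mult_2": int((mult == 2).sum()),
                    "mult_3plus": int((mult >= 3).sum()),
                    "total_sites": int(len(sub)),
                    "n_phosphoproteins": int(sub["protein_id"].nunique()) if len(sub) else 0,
                }
            )
    return pd.DataFrame(rows).set_index(["subtype", "tissue"])


def site_feature_id(protein_id: str, residue: str, position: int, multiplicity: int) -> str:
    return f"{protein_id}:{residue}{int(position)}:{int(multiplicity)}"


def site_matrix(T: PhosphoSiteTable) -> IntensityMatrix:
    """Bridge site rows to the shared intensity-matrix machinery.

    Feature ids are ``protein:S<pos>:<multiplicity>``; duplicates are an
    invariant violation upstream and raise.
    """
    ids = [
        site_feature_id(r.protein_id, r.residue, r.position, r.multiplicity)
        for r in T.sites.itertuples()
    ]
    data = T.intensities.copy()
    data.index = pd.Index(ids, name="feature_id")
    return IntensityMatrix(data, "linear")


def site_gene_map(T: PhosphoSiteTable) -> dict[str, tuple[str, str]]:
    """feature_id -> (gene symbol, site string) for kinase-substrate joins.

    Falls back to the protein id when no gene symbol was provided.
    """
    out: dict[str, tuple[str, str]] = {}
    for r in T.sites.itertuples():
        fid = site_feature_id(r.protein_id, r.residue, r.position, r.multiplicity)
        gene = (r.gene or r.protein_id).upper()
        out[fid] = (gene, f"{r.residue}{int(r.position)}")
    return out


def _protein_of(feature_id: str) -> str:
    return feature_id.rsplit(":", 2)[0]


def aggregate_protein_phospho_fc(site_diff: pd.DataFrame, agg_method: str = "median") -> pd.DataFrame:
    """Collapse site-level screen results to one phospho FC per protein.

    Input is the site-level :func:`~phosphopair.paired_differential.differential_screen`
    table (indexed by ``protein:S<pos>:<mult>`` feature ids).  Output per
    protein: ``mean_fc`` (exponentiated median of site log2 FCs), ``best_p``
    (minimum site p) and ``n_sites``.  Sites whose mean FC is undefined are
    skipped; proteins with no surviving site are absent.
    """
    if agg_method not in ("median", "mean"):
        raise ValueError(f"unknown agg_method {agg_method!r}")
    usable = site_diff[np.isfinite(site_diff["mean_fc"])]
    proteins = usable.index.map(_protein_of)
    rows = []
    for protein, grp in usable.groupby(proteins):
        log2fcs = np.log2(grp["mean_fc"].to_numpy(dtype=float))
        agg = np.median(log2fcs) if agg_method == "median" else np.mean(log2fcs)
        pvals = grp["welch_p"].dropna()
        rows.append(
            {
                "protein_id": protein,
                "mean_fc": float(2.0 ** agg),
                "best_p": float(pvals.min()) if len(pvals) else np.nan,
                "n_sites": int(len(grp)),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "mean_fc", "best_p", "n_sites"]).set_index("protein_id")


def differential_phosphoproteins(site_diff: pd.DataFrame) -> set[str]:
    """Proteins with at least one site called up or down."""
    called = site_diff[site_diff["call"] != "ns"]
    return {_protein_of(fid) for fid in called.index}
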
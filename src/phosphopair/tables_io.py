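"""Readers and writers for the tab-separated tables the pipeline consumes.

The pipeline ingests search-engine output in the MaxQuant dialect: a
``proteinGroups``-style table with one ``Intensity <sample>`` column per
sample, and a ``Phospho (STY)Sites``-style table where each site carries
per-sample intensities split by phosphopeptide multiplicity through the
``___1``/``___2``/``___3`` column-name suffixes.  Kinase-substrate
annotations are read in the PhosphoSitePlus ``Kinase_Substrate_Dataset``
dialect.  Every table is re-emitted as plain TSV.

MaxQuant writes an intensity of 0 when a feature was not observed in a
sample; those zeros are converted to missing on read and restored to 0 on
write, so a round trip through the dialect preserves missingness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TISSUES = ("tumor", "NAT")
SUBTYPES = ("IDC", "ILC")

#: Multiplicity classes split out by the ``___k`` suffix convention.
MULTIPLICITY_CLASSES = (1, 2, 3)


class TableFormatError(ValueError):
    """An input table violates the dialect or an internal invariant."""


# ---------------------------------------------------------------------------
# paired design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedDesign:
    """Sample design: one tumor and one NAT sample per patient.

    ``entries`` has columns ``sample``, ``patient``, ``tissue``
    (tumor/NAT) and ``subtype`` (IDC/ILC).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        required = {"sample", "patient", "tissue", "subtype"}
        missing = required - set(df.columns)
        if missing:
            raise TableFormatError(f"design is missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise TableFormatError("no samples in design")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise TableFormatError(f"duplicate sample id {dup!r}")
        bad_tissue = set(df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise TableFormatError(f"unknown tissue label(s): {sorted(bad_tissue)}")
        bad_sub = set(df["subtype"]) - set(SUBTYPES)
        if bad_sub:
            raise TableFormatError(f"unknown subtype label(s): {sorted(bad_sub)}")
        for patient, grp in df.groupby("patient", sort=False):
            tissues = sorted(grp["tissue"])
            if tissues != sorted(TISSUES):
                raise TableFormatError(
                    f"patient {patient!r} is not a tumor/NAT pair (has {tissues})"
                )
            if grp["subtype"].nunique() != 1:
                raise TableFormatError(f"patient {patient!r} has conflicting subtypes")

    # -- look-ups -----------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries["sample"])

    def patients(self, subtype: str | None = None) -> list[str]:
        df = self.entries
        if subtype is not None:
            df = df[df["subtype"] == subtype]
        seen: list[str] = []
        for p in df["patient"]:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def n_pairs(self) -> int:
        return len(self.patients())

    def subtype_of(self, patient: str) -> str:
        df = self.entries
        rows = df[df["patient"] == patient]
        if rows.empty:
            raise KeyError(patient)
        return rows["subtype"].iloc[0]

    def sample_of(self, patient: str, tissue: str) -> str:
        df = self.entries
        rows = df[(df["patient"] == patient) & (df["tissue"] == tissue)]
        if rows.empty:
            raise KeyError((patient, tissue))
        return rows["sample"].iloc[0]

    def samples(self, subtype: str | None = None, tissue: str | None = None) -> list[str]:
        df = self.entries
        if subtype is not None:
            df = df[df["subtype"] == subtype]
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        return list(df["sample"])


def read_design(path: str | Path) -> PairedDesign:
    """Read a TSV/CSV sample-design table (columns sample, patient, tissue, subtype)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise TableFormatError("no samples in design")
    df.columns = [c.strip().lower() for c in df.columns]
    return PairedDesign(df[["sample", "patient", "tissue", "subtype"]].copy())


def write_design(design: PairedDesign, path: str | Path) -> None:
    design.entries.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intensity matrix
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Features x samples abundance grid; NaN marks missing.

    ``scale`` is ``"linear"`` (non-negative peak areas) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        values = self.data.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if not np.isfinite(values[present]).all():
            raise TableFormatError("non-finite present value in intensity matrix")
        if self.scale == "linear" and (values[present] < 0).any():
            raise TableFormatError("negative value in linear-scale intensity matrix")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableFormatError(f"duplicate feature id {dup!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def present_mask(self) -> pd.DataFrame:
        return self.data.notna()

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), self.scale)


def write_matrix(X: IntensityMatrix, path: str | Path) -> None:
    """Write an IntensityMatrix as TSV; missing cells are empty fields."""
    with open(path, "w") as fh:
        fh.write(f"# scale={X.scale}\n")
        X.data.to_csv(fh, sep="\t", index_label="feature_id", na_rep="")


def read_matrix(path: str | Path) -> IntensityMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        m = re.match(r"#\s*scale=(\w+)", first)
        if not m:
            raise TableFormatError(f"{path}: missing '# scale=' header line")
        df = pd.read_csv(fh, sep="\t", index_col="feature_id")
    return IntensityMatrix(df.astype(float), m.group(1))


# ---------------------------------------------------------------------------
# proteinGroups dialect
# ---------------------------------------------------------------------------


def _flagged(df: pd.DataFrame, column: str) -> pd.Series:
    if column in df.columns:
        return df[column].astype(str).str.strip() == "+"
    return pd.Series(False, index=df.index)


def read_protein_table(
    path: str | Path,
    design: PairedDesign,
    intensity_prefix: str = "Intensity",
) -> IntensityMatrix:
    """Read a proteinGroups-dialect TSV into a linear-scale IntensityMatrix.

    Reverse-decoy and potential-contaminant rows are dropped, zeros become
    missing, and the feature id is the first accession of the
    ``Majority protein IDs`` field.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = "Majority protein IDs" if "Majority protein IDs" in df.columns else "Protein IDs"
    if id_col not in df.columns:
        raise TableFormatError("no 'Majority protein IDs' or 'Protein IDs' column")
    keep = ~(_flagged(df, "Reverse") | _flagged(df, "Potential contaminant"))
    df = df[keep]

    wanted = {sid: f"{intensity_prefix} {sid}" for sid in design.sample_ids}
    absent = [sid for sid, col in wanted.items() if col not in df.columns]
    if absent:
        raise TableFormatError(f"no intensity column for sample(s): {absent}")

    values = df[[wanted[sid] for sid in design.sample_ids]].astype(float)
    values.columns = design.sample_ids
    values = values.mask(values == 0.0)  # MaxQuant zero == not observed
    values.index = [str(ids).split(";")[0] for ids in df[id_col]]
    values.index.name = "feature_id"
    return IntensityMatrix(values, "linear")


def write_protein_table(X: IntensityMatrix, path: str | Path,
                        intensity_prefix: str = "Intensity") -> None:
    """Emit a linear-scale matrix in the proteinGroups dialect (missing -> 0)."""
    if X.scale != "linear":
        raise ValueError("protein table must be written on the linear scale")
    out = pd.DataFrame({"Majority protein IDs": X.feature_ids})
    out["Reverse"] = ""
    out["Potential contaminant"] = ""
    vals = X.data.fillna(0.0)
    for sid in X.sample_ids:
        out[f"{intensity_prefix} {sid}"] = vals[sid].to_numpy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phospho (STY)Sites dialect
# ---------------------------------------------------------------------------


@dataclass
class PhosphoSiteTable:
    """Site-level phospho records, one row per (site, multiplicity class).

    ``sites`` columns: protein_id, gene, residue, position,
    localization_prob, multiplicity, reverse_flag, contaminant_flag.
    ``intensities`` shares the index and holds per-sample linear abundances
    (NaN missing).
    """

    sites: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.intensities.index):
            raise TableFormatError("site and intensity tables are misaligned")
        bad_res = set(self.sites["residue"]) - {"S", "T", "Y"}
        if bad_res:
            raise TableFormatError(f"unknown residue(s): {sorted(bad_res)}")
        if (self.sites["position"] < 1).any():
            raise TableFormatError("phosphosite position must be >= 1")
        probs = self.sites["localization_prob"]
        if ((probs < 0) | (probs > 1)).any():
            raise TableFormatError("localization probability outside [0, 1]")
        key = self.sites[["protein_id", "position", "multiplicity"]]
        if key.duplicated().any():
            raise TableFormatError("duplicate (protein, position, multiplicity) row")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def subset(self, mask: pd.Series) -> "PhosphoSiteTable":
        return PhosphoSiteTable(
            self.sites[mask].reset_index(drop=True),
            self.intensities[mask].reset_index(drop=True),
        )


def read_phospho_table(
    path: str | Path,
    design: PairedDesign,
    intensity_prefix: str = "Intensity",
) -> PhosphoSiteTable:
    """Read a Phospho(STY)Sites-dialect TSV.

    The ``___k`` suffix splits each sample's intensity by how many phosphate
    groups the quantified peptide carried; each (site, multiplicity) with at
    least one observed intensity becomes one row.  No localization-probability
    filtering happens here — that is a separate, explicit stage.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("Amino acid", "Position", "Localization prob"):
        if col not in df.columns:
            raise TableFormatError(f"phospho table is missing column {col!r}")
    if "Protein" in df.columns:
        proteins = df["Protein"].astype(str)
    elif "Proteins" in df.columns:
        proteins = df["Proteins"].astype(str).str.split(";").str[0]
    else:
        raise TableFormatError("phospho table is missing a 'Protein' column")
    genes = (
        df["Gene names"].fillna("").astype(str).str.split(";").str[0]
        if "Gene names" in df.columns
        else pd.Series("", index=df.index)
    )

    positions = np.empty(len(df), dtype=int)
    for i, (idx, raw) in enumerate(df["Position"].items()):
        try:
            positions[i] = int(str(raw))
        except (TypeError, ValueError):
            # +2: one for the header line, one for 0- vs 1-based
            raise TableFormatError(
                f"malformed position {raw!r} at file row {idx + 2}"
            ) from None

    reverse = _flagged(df, "Reverse").to_numpy()
    contam = _flagged(df, "Potential contaminant").to_numpy()

    site_rows: list[dict] = []
    intensity_rows: list[np.ndarray] = []
    sample_ids = design.sample_ids
    for mult in MULTIPLICITY_CLASSES:
        cols = {sid: f"{intensity_prefix} {sid}___{mult}" for sid in sample_ids}
        if not all(c in df.columns for c in cols.values()):
            continue
        block = df[[cols[sid] for sid in sample_ids]].astype(float)
        block = block.mask(block == 0.0)
        observed = block.notna().any(axis=1).to_numpy()
        for i in np.flatnonzero(observed):
            site_rows.append(
                {
                    "protein_id": proteins.iloc[i],
                    "gene": genes.iloc[i],
                    "residue": str(df["Amino acid"].iloc[i]).strip(),
                    "position": positions[i],
                    "localization_prob": float(df["Localization prob"].iloc[i]),
                    "multiplicity": mult,
                    "reverse_flag": bool(reverse[i]),
                    "contaminant_flag": bool(contam[i]),
                }
            )
            intensity_rows.append(block.iloc[i].to_numpy())

    sites = pd.DataFrame(
        site_rows,
        columns=[
            "protein_id", "gene", "residue", "position", "localization_prob",
            "multiplicity", "reverse_flag", "contaminant_flag",
        ],
    )
    if len(sites) == 0:
        intens = pd.DataFrame(columns=sample_ids, dtype=float)
    else:
        intens = pd.DataFrame(intensity_rows, columns=sample_ids)
    sites = sites.astype(
        {"position": int, "multiplicity": int, "localization_prob": float}
    ) if len(sites) else sites
    return PhosphoSiteTable(sites.reset_index(drop=True), intens.reset_index(drop=True))


def write_phospho_table(T: PhosphoSiteTable, path: str | Path,
                        intensity_prefix: str = "Intensity") -> None:
    """Emit a PhosphoSiteTable in the Phospho(STY)Sites dialect.

    Rows sharing (protein, position) but differing in multiplicity fold back
    into one file row with ``___k`` columns; unobserved cells become 0.
    """
    sample_ids = T.sample_ids
    groups: dict[tuple, dict] = {}
    for i in range(len(T)):
        s = T.sites.iloc[i]
        key = (s["protein_id"], s["position"])
        rec = groups.setdefault(
            key,
            {
                "Protein": s["protein_id"],
                "Gene names": s["gene"],
                "Amino acid": s["residue"],
                "Position": int(s["position"]),
                "Localization prob": s["localization_prob"],
                "Reverse": "+" if s["reverse_flag"] else "",
                "Potential contaminant": "+" if s["contaminant_flag"] else "",
            },
        )
        vals = T.intensities.iloc[i].fillna(0.0)
        for sid in sample_ids:
            rec[f"{intensity_prefix} {sid}___{int(s['multiplicity'])}"] = vals[sid]
    out = pd.DataFrame(list(groups.values()))
    for mult in MULTIPLICITY_CLASSES:
        for sid in sample_ids:
            col = f"{intensity_prefix} {sid}___{mult}"
            if col not in out.columns:
                out[col] = 0.0
            else:
                out[col] = out[col].fillna(0.0)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kinase-substrate annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinaseSubstrateTable:
    """Deduplicated (kinase, substrate gene, site) triples.

    Gene symbols are upper-cased so joins against quantification tables are
    case-insensitive; sites use the residue-letter-plus-position string of
    the PhosphoSitePlus ``SUB_MOD_RSD`` convention (e.g. ``"S473"``).
    """

    triples: pd.DataFrame  # columns kinase, substrate_protein, site

    def __post_init__(self) -> None:
        if self.triples.duplicated().any():
            raise TableFormatError("duplicate kinase-substrate triple")

    def __len__(self) -> int:
        return len(self.triples)

    @property
    def kinases(self) -> list[str]:
        seen: list[str] = []
        for k in self.triples["kinase"]:
            if k not in seen:
                seen.append(k)
        return seen

    def substrates_of(self, kinase: str) -> set[tuple[str, str]]:
        df = self.triples
        rows = df[df["kinase"] == kinase.upper()]
        return set(zip(rows["substrate_protein"], rows["site"]))


def read_kinase_substrates(
    path: str | Path, organism_filter: str | None = None
) -> KinaseSubstrateTable:
    """Read a PhosphoSitePlus Kinase_Substrate_Dataset-dialect TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    kin_col = "GENE" if "GENE" in df.columns else "KINASE"
    if kin_col not in df.columns:
        raise TableFormatError("kinase-substrate table is missing column 'GENE'/'KINASE'")
    for col in ("SUB_GENE", "SUB_MOD_RSD"):
        if col not in df.columns:
            raise TableFormatError(f"kinase-substrate table is missing column {col!r}")
    if organism_filter is not None:
        want = organism_filter.strip().lower()
        for col in ("KIN_ORGANISM", "SUB_ORGANISM"):
            if col in df.columns:
                df = df[df[col].astype(str).str.strip().str.lower() == want]
    triples = pd.DataFrame(
        {
            "kinase": df[kin_col].astype(str).str.strip().str.upper(),
            "substrate_protein": df["SUB_GENE"].astype(str).str.strip().str.upper(),
            "site": df["SUB_MOD_RSD"].astype(str).str.strip().str.upper(),
        }
    )
    triples = triples.drop_duplicates().reset_index(drop=True)
    return KinaseSubstrateTable(triples)


def write_kinase_substrates(table: KinaseSubstrateTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "GENE": table.triples["kinase"],
            "KINASE": table.triples["kinase"],
            "KIN_ORGANISM": "human",
            "SUB_GENE": table.triples["substrate_protein"],
            "SUB_MOD_RSD": table.triples["site"],
            "SUB_ORGANISM": "human",
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------


ND = "ND"  # not detected at the phospho layer


@dataclass(frozen=True)
class Table2Fixture:
    """The 13 dual-subtype differential proteins with their printed tumor/NAT
    fold changes at the protein and phosphorylation layers (ND = the protein
    was not a differential phosphoprotein)."""

    rows: pd.DataFrame  # protein_label, prot_fc_idc, prot_fc_ilc, phos_fc_idc, phos_fc_ilc

    def __post_init__(self) -> None:
        if len(self.rows) != 13:
            raise TableFormatError("fixture must have exactly 13 rows")
        nd = self.rows["phos_fc_idc"].isna()
        if nd.sum() != 3 or (nd != self.rows["phos_fc_ilc"].isna()).any():
            raise TableFormatError("fixture must have exactly 3 ND phospho rows")

    def dual_layer(self) -> pd.DataFrame:
        """The 10 rows quantified at both layers."""
        return self.rows[self.rows["phos_fc_idc"].notna()].reset_index(drop=True)


def _data_path(name: str):
    return resources.files("phosphopair") / "data" / name


def load_table2_fixture() -> Table2Fixture:
    with resources.as_file(_data_path("table2.csv")) as p:
        df = pd.read_csv(p, na_values=[ND])
    for col in ("prot_fc_idc", "prot_fc_ilc", "phos_fc_idc", "phos_fc_ilc"):
        df[col] = df[col].astype(float)
    return Table2Fixture(df)


def load_kinome_groups() -> dict[str, str]:
    """Kinase gene symbol -> kinome group (AGC, CAMK, CK1, CMGC, STE, TK,
    TKL, RGC, Atypical, Other)."""
    with resources.as_file(_data_path("kinome_groups.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return {str(k).upper(): str(g) for k, g in zip(df["kinase"], df["group"])}


def load_toy_kinase_substrates() -> KinaseSubstrateTable:
    """Small curated human kinase-substrate annotation bundle used by the
    synthetic-data defaults and the documentation examples."""
    with resources.as_file(_data_path("kinase_substrates_toy.tsv")) as p:
        return read_kinase_substrates(p)
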
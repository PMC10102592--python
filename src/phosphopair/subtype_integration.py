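"""Cross-subtype integration: quadrant classification of dual-subtype
differential proteins and protein-vs-phospho discordance grouping.

A protein differential in both subtypes falls into one of five quadrants of
the (IDC fold change, ILC fold change) plane; the two discordant quadrants
(up in one subtype, down in the other) are the interesting ones.  Proteins
quantified at both the protein and the phosphorylation layer get a 4-state
signature (protein-IDC, protein-ILC, phospho-IDC, phospho-ILC), each state
up / down / maintained, and signatures are matched against three discordance
patterns:

* G1 — protein up in both subtypes, phosphorylation up in IDC but down in
  ILC (the signature that separates the subtypes most cleanly);
* G2 — protein not down in either subtype, phosphorylation down in IDC and
  not down in ILC;
* G3 — protein maintained in IDC and up in ILC, phosphorylation down or
  maintained in IDC and maintained or up in ILC.

When fold changes come from a table printed at 2 decimal places the state
thresholds are applied inclusively (up: FC >= 1.5, down: FC <= 0.67), since
0.67 is itself the rounded 1/1.5; full-precision pipeline values use strict
inequalities.  A signature can match more than one pattern: assignment takes
the first match in G1, G2, G3 order and all matches are reported so pattern
overlaps are visible rather than silently resolved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .paired_differential import ScreenConfig
from .tables_io import Table2Fixture

QUADRANTS = ("both_up", "both_down", "idc_up_ilc_down", "idc_down_ilc_up", "other")
GROUPS = ("G1", "G2", "G3")


# ---------------------------------------------------------------------------
# quadrants
# ---------------------------------------------------------------------------


def quadrant_classify(fc_idc: float, fc_ilc: float, cfg: ScreenConfig = ScreenConfig()) -> str:
    if not (fc_idc > 0 and fc_ilc > 0):
        raise ValueError("fold changes must be positive")
    up_i, up_l = fc_idc > cfg.fc_up, fc_ilc > cfg.fc_up
    dn_i, dn_l = fc_idc < cfg.fc_down, fc_ilc < cfg.fc_down
    if up_i and up_l:
        return "both_up"
    if dn_i and dn_l:
        return "both_down"
    if up_i and dn_l:
        return "idc_up_ilc_down"
    if dn_i and up_l:
        return "idc_down_ilc_up"
    return "other"


def quadrant_table(fcs: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Add a ``quadrant`` column to a table with ``fc_idc``/``fc_ilc``."""
    out = fcs.copy()
    out["quadrant"] = [
        quadrant_classify(i, l, cfg) for i, l in zip(out["fc_idc"], out["fc_ilc"])
    ]
    return out


def opposite_direction_counts(
    fcs: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()
) -> tuple[int, int]:
    """(#idc_up_ilc_down, #idc_down_ilc_up) from a fc_idc/fc_ilc table."""
    q = quadrant_table(fcs, cfg)["quadrant"]
    return int((q == "idc_up_ilc_down").sum()), int((q == "idc_down_ilc_up").sum())


def overlap_diff_protein_phospho(
    diff_proteins: set[str], diff_phosphoproteins: set[str]
) -> tuple[int, int, int]:
    """(n_both, n_protein_only, n_phospho_only)."""
    both = diff_proteins & diff_phosphoproteins
    return (
        len(both),
        len(diff_proteins - diff_phosphoproteins),
        len(diff_phosphoproteins - diff_proteins),
    )


# ---------------------------------------------------------------------------
# discordance signatures
# ---------------------------------------------------------------------------


def layer_state(fc: float, cfg: ScreenConfig = ScreenConfig(), inclusive: bool = False) -> str:
    """up / down / maintained for one fold change.

    ``inclusive`` is for fold changes printed at 2 decimal places: the
    comparison happens at that precision with inclusive bounds, so 0.67
    (the rounded 1/1.5) counts as down and 1.50 as up.
    """
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError(f"fold change must be positive and finite, got {fc!r}")
    if inclusive:
        if round(fc, 2) >= round(cfg.fc_up, 2):
            return "up"
        if round(fc, 2) <= round(cfg.fc_down, 2):
            return "down"
    else:
        if fc > cfg.fc_up:
            return "up"
        if fc < cfg.fc_down:
            return "down"
    return "maintained"


def _matches_g1(s: tuple[str, str, str, str]) -> bool:
    return s == ("up", "up", "up", "down")


def _matches_g2(s: tuple[str, str, str, str]) -> bool:
    pi, pl, hi, hl = s
    return pi != "down" and pl != "down" and hi == "down" and hl != "down"


def _matches_g3(s: tuple[str, str, str, str]) -> bool:
    pi, pl, hi, hl = s
    return pi == "maintained" and pl == "up" and hi != "up" and hl != "down"


_PATTERNS = {"G1": _matches_g1, "G2": _matches_g2, "G3": _matches_g3}


def discordance_groups(signatures: pd.DataFrame) -> pd.DataFrame:
    """Assign discordance groups to 4-state signatures.

    Input columns: ``prot_idc``, ``prot_ilc``, ``phos_idc``, ``phos_ilc``
    (each up/down/maintained).  Output adds ``group`` (first matching
    pattern, or ``unassigned``) and ``matches`` (comma-joined list of every
    matching pattern).
    """
    groups, matches = [], []
    for row in signatures.itertuples():
        state = (row.prot_idc, row.prot_ilc, row.phos_idc, row.phos_ilc)
        hit = [g for g in GROUPS if _PATTERNS[g](state)]
        groups.append(hit[0] if hit else "unassigned")
        matches.append(",".join(hit))
    out = signatures.copy()
    out["group"] = groups
    out["matches"] = matches
    return out


def table2_signatures(fixture: Table2Fixture, cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """4-state signatures for the fixture's 10 dual-layer rows
    (inclusive thresholds: the printed values are 2-dp rounded)."""
    dual = fixture.dual_layer()
    sig = pd.DataFrame(index=dual["protein_label"])
    for col, src in (
        ("prot_idc", "prot_fc_idc"),
        ("prot_ilc", "prot_fc_ilc"),
        ("phos_idc", "phos_fc_idc"),
        ("phos_ilc", "phos_fc_ilc"),
    ):
        sig[col] = [layer_state(v, cfg, inclusive=True) for v in dual[src]]
    return sig


def table2_quadrants(fixture: Table2Fixture, cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    fcs = pd.DataFrame(
        {
            "fc_idc": fixture.rows["prot_fc_idc"].to_numpy(),
            "fc_ilc": fixture.rows["prot_fc_ilc"].to_numpy(),
        },
        index=fixture.rows["protein_label"],
    )
    return quadrant_table(fcs, cfg)
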
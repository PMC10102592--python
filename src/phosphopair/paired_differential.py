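"""Three-criterion paired tumor/NAT differential screen, per subtype.

A feature is called up-regulated in a subtype when all three hold:

* two-tailed Welch (unequal-variance) t-test p < 0.05 between the subtype's
  tumor and NAT samples on the log2 scale;
* subtype mean tumor/NAT fold change > 1.50 (down: < 0.67 = 1/1.5);
* strictly more than 60% of the patient pairs with both members observed
  individually reach the fold-change threshold in the same direction
  (4+ of 5 pairs at full presence).

Thresholds live in :class:`ScreenConfig`; the strict ">" reading of both
percentage criteria (concordance and the patient-coverage prefilter) follows
from their being stated together with "more than 3 pairs of the 5".
Missing values are excluded throughout: a pair with either member missing
contributes no fold change, and concordance fractions use present pairs as
the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import IntensityMatrix, PairedDesign


@dataclass(frozen=True)
class ScreenConfig:
    p_threshold: float = 0.05
    fc_up: float = 1.50
    fc_down: float = 1.0 / 1.5  # displayed 0.67
    concordance_fraction: float = 0.60  # strict ">"
    min_pair_coverage_fraction: float = 0.60  # strict ">"
    mean_method: str = "geometric"  # or "arithmetic"
    paired_test: bool = False  # paired t instead of the Welch default

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.fc_up <= 1:
            raise ValueError("fc_up must exceed 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must be in (0, 1)")
        for frac in (self.concordance_fraction, self.min_pair_coverage_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must be in (0, 1)")
        if self.mean_method not in ("geometric", "arithmetic"):
            raise ValueError(f"unknown mean_method {self.mean_method!r}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def patient_coverage_filter(
    X: IntensityMatrix, design: PairedDesign, cfg: ScreenConfig = ScreenConfig()
) -> IntensityMatrix:
    """Keep features observed in both members of strictly more than
    ``min_pair_coverage_fraction`` of all patient pairs."""
    present = X.present_mask()
    patients = design.patients()
    pair_present = pd.DataFrame(
        {
            p: present[design.sample_of(p, "tumor")] & present[design.sample_of(p, "NAT")]
            for p in patients
        }
    )
    n_covered = pair_present.sum(axis=1)
    keep = n_covered > cfg.min_pair_coverage_fraction * len(patients)
    return IntensityMatrix(X.data[keep.to_numpy()], X.scale)


def pair_fold_changes(
    X: IntensityMatrix, design: PairedDesign, subtype: str
) -> pd.DataFrame:
    """Per-patient linear tumor/NAT ratios (feature x patient; NaN where
    either pair member is missing)."""
    if X.scale != "linear":
        raise ValueError("pair_fold_changes expects a linear-scale matrix")
    out = {}
    for patient in design.patients(subtype):
        tumor = X.data[design.sample_of(patient, "tumor")]
        nat = X.data[design.sample_of(patient, "NAT")]
        out[patient] = tumor / nat
    return pd.DataFrame(out, index=X.data.index)


def welch_test(X: IntensityMatrix, design: PairedDesign, subtype: str) -> pd.Series:
    """Two-tailed Welch t-test p per feature, tumor group vs NAT group
    within the subtype, on log2 intensities.

    Features with fewer than 2 present values in either group get NaN
    (uncallable).  Identical groups with zero spread get p = 1.
    """
    if X.scale != "log2":
        raise ValueError("welch_test expects a log2-scale matrix")
    tumor = X.data[design.samples(subtype, "tumor")].to_numpy(dtype=float)
    nat = X.data[design.samples(subtype, "NAT")].to_numpy(dtype=float)

    n1 = (~np.isnan(tumor)).sum(axis=1)
    n2 = (~np.isnan(nat)).sum(axis=1)
    enough = (n1 >= 2) & (n2 >= 2)

    p = np.full(X.data.shape[0], np.nan)
    if enough.any():
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # zero-spread rows trip scipy's precision warning; they are
            # resolved explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                tumor[enough], nat[enough], axis=1,
                equal_var=False, nan_policy="omit",
            )
        pv = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance: t is 0/0; equal groups mean p = 1,
        # distinct means with zero spread mean p -> 0
        m1 = np.nanmean(tumor[enough], axis=1)
        m2 = np.nanmean(nat[enough], axis=1)
        v1 = np.nanvar(tumor[enough], axis=1, ddof=1)
        v2 = np.nanvar(nat[enough], axis=1, ddof=1)
        degen = (v1 == 0) & (v2 == 0)
        pv[degen & (m1 == m2)] = 1.0
        pv[degen & (m1 != m2)] = 0.0
        p[enough] = pv
    return pd.Series(p, index=X.data.index, name="welch_p")


def concordance_fractions(
    pair_fcs, cfg: ScreenConfig = ScreenConfig()
) -> tuple[float, float]:
    """(frac_up, frac_down) for one feature's pair fold changes.

    A pair counts toward frac_up when its FC reaches ``fc_up`` (>=) and
    toward frac_down when it reaches ``fc_down`` (<=); the denominator is
    the number of present pairs.
    """
    fcs = np.asarray(pd.Series(pair_fcs).dropna(), dtype=float)
    if fcs.size == 0:
        return (np.nan, np.nan)
    return (
        float(np.mean(fcs >= cfg.fc_up)),
        float(np.mean(fcs <= cfg.fc_down)),
    )


def call_differential(
    mean_fc: float,
    welch_p: float,
    fractions: tuple[float, float],
    cfg: ScreenConfig = ScreenConfig(),
) -> str:
    """Combine the three criteria into an up/down/ns call."""
    frac_up, frac_down = fractions
    if not (np.isfinite(mean_fc) and np.isfinite(welch_p)):
        return "ns"
    if welch_p < cfg.p_threshold:
        if mean_fc > cfg.fc_up and np.isfinite(frac_up) and frac_up > cfg.concordance_fraction:
            return "up"
        if mean_fc < cfg.fc_down and np.isfinite(frac_down) and frac_down > cfg.concordance_fraction:
            return "down"
    return "ns"


def _paired_test(X: IntensityMatrix, design: PairedDesign, subtype: str) -> pd.Series:
    """Paired t on per-pair log2 differences (optional alternative)."""
    tumor = X.data[[design.sample_of(p, "tumor") for p in design.patients(subtype)]]
    nat = X.data[[design.sample_of(p, "NAT") for p in design.patients(subtype)]]
    diffs = tumor.to_numpy(dtype=float) - nat.to_numpy(dtype=float)
    p = np.full(diffs.shape[0], np.nan)
    for i, row in enumerate(diffs):
        row = row[~np.isnan(row)]
        if row.size >= 2:
            if np.ptp(row) == 0:
                p[i] = 1.0 if row[0] == 0 else 0.0
            else:
                p[i] = stats.ttest_1samp(row, 0.0).pvalue
    return pd.Series(p, index=X.data.index, name="welch_p")


def differential_screen(
    X_log2: IntensityMatrix,
    design: PairedDesign,
    subtype: str,
    cfg: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Run the full three-criterion screen for one subtype.

    Returns one row per feature: per-pair fold changes (``fc_<patient>``),
    subtype mean fold change, Welch p, concordance fractions and the call.
    """
    fcs = pair_fold_changes(to_linear_view(X_log2), design, subtype)
    log2fc = np.log2(fcs)
    if cfg.mean_method == "geometric":
        mean_fc = 2.0 ** log2fc.mean(axis=1, skipna=True)
    else:
        mean_fc = fcs.mean(axis=1, skipna=True)
    n_present = fcs.notna().sum(axis=1)
    mean_fc[n_present == 0] = np.nan

    p = _paired_test(X_log2, design, subtype) if cfg.paired_test else welch_test(
        X_log2, design, subtype)

    frac_up = (fcs >= cfg.fc_up).sum(axis=1) / n_present.replace(0, np.nan)
    frac_down = (fcs <= cfg.fc_down).sum(axis=1) / n_present.replace(0, np.nan)

    calls = [
        call_differential(mf, pv, (fu, fd), cfg)
        for mf, pv, fu, fd in zip(mean_fc, p, frac_up, frac_down)
    ]
    out = pd.DataFrame(index=X_log2.data.index)
    out["subtype"] = subtype
    for patient in fcs.columns:
        out[f"fc_{patient}"] = fcs[patient]
    out["n_present_pairs"] = n_present
    out["mean_fc"] = mean_fc
    out["welch_p"] = p
    out["frac_up"] = frac_up
    out["frac_down"] = frac_down
    out["call"] = calls
    return out


def to_linear_view(X: IntensityMatrix) -> IntensityMatrix:
    """Linear-scale view of a matrix in either scale."""
    if X.scale == "linear":
        return X
    return IntensityMatrix(2.0 ** X.data, "linear")
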
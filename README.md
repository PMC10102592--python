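# phosphopair

Paired tumor/normal differential analysis for label-free quantitative
proteomics and phosphoproteomics, with kinase-activity inference.

The package targets the common clinical-proteomics design in which each
patient contributes one tumor and one adjacent-normal (NAT) tissue sample
and patients split into two histological subtypes — here invasive ductal
(IDC) versus invasive lobular (ILC) luminal A breast cancer, five pairs
each.  It takes MaxQuant-style `proteinGroups` and `Phospho (STY)Sites`
tables plus a PhosphoSitePlus-style kinase–substrate table and runs:

1. **Normalization** — per-sample median-centering of log2 intensities to
   the grand median (total-intensity variant available); MaxQuant zeros are
   treated as missing throughout.
2. **Three-criterion paired screen**, per subtype: a feature is called up
   when the two-tailed Welch t-test gives p < 0.05 between tumor and NAT
   groups, the subtype mean tumor/NAT fold change exceeds 1.50 (down:
   < 0.67 = 1/1.5), **and** strictly more than 60 % of the observed patient
   pairs individually reach the threshold in the same direction (4+ of 5
   pairs).  A >60 % patient-coverage prefilter removes features missing in
   too many pairs.
3. **Phosphosite processing** — class-I filtering (localization
   probability > 0.75), per-multiplicity quantification (the MaxQuant
   `___1/___2/___3` convention), and aggregation of site-level fold changes
   to one phosphorylation fold change per protein (median of site log2
   fold changes).
4. **Subtype integration** — quadrant classification of dual-subtype
   fold changes, protein-versus-phosphoprotein overlap, and discordance
   signatures (protein state × phospho state in both subtypes).
5. **KSEA** — kinase activity scored as
   `z = (s̄ − p̄)·√m / δ`, where `s̄` is the mean log2 fold change over the
   kinase's `m` quantified substrate sites and `p̄`, `δ` are the mean and
   sample SD over all quantified sites; two-tailed normal p-value,
   significance at p < 0.05 with ≥ 3 substrates, kinome-group annotation
   (AGC, CAMK, CK1, CMGC, STE, TK, TKL, RGC, Atypical, Other).

A synthetic-data module generates complete cohorts with known ground truth
(planted differential proteins, planted kinase activations, per-sample
scale biases, missing-not-at-random dropout), so every stage is testable
without any raw mass-spectrometry data.

## Worked example

The package bundles the 13 dual-subtype differential proteins with their
printed protein- and phospho-layer tumor/NAT fold changes.  The analysis
scripts run the whole chain on a synthetic cohort and on that table:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_protein_screen.py
python analysis/04_table2_integration.py
```

prints, among other lines:

```
1000 proteins read, 845 pass the >60% pair-coverage filter
IDC: 45 up, 34 down; recalled 75/100 planted proteins (79 total calls)
up in IDC / down in ILC: 1; down in IDC / up in ILC: 2
quantified at both layers: 10
discordance group G1 (protein up both, phospho up-IDC/down-ILC):
    ['KTN1_HUMAN', 'ROA1_HUMAN', 'SEPT2_HUMAN', 'SEPT9_HUMAN']
```

Reading: of the 13 proteins differential in both subtypes, exactly one
(histone H1.10) is up in IDC but down in ILC and two (complement C4-B,
CRKL) are down in IDC but up in ILC; ten are also differential at the
phosphorylation layer; and four of those ten (the two septins, hnRNP A1
and kinectin) share the G1 signature — protein up in both subtypes while
phosphorylation rises in IDC and falls in ILC — the combination that
separates the two subtypes most cleanly.  `analysis/05_ksea.py` then
recovers the two planted kinase shifts (AKT1 activated, MAPK3 inactivated)
as the only significant kinases, in the planted subtype only.

The same pipeline is available as a CLI (`phosphopair simulate | run |
ksea | table2-report`) driven by a YAML config; exit codes are 0/1/2 for
ok/usage error/data error.

## Output tables

All stage outputs are plain TSV/JSON with fixed column orders:

| file | columns |
|---|---|
| `protein_screen_<subtype>.tsv`, `site_screen_<subtype>.tsv` | feature_id, subtype, fc_&lt;patient&gt;…, n_present_pairs, mean_fc, welch_p, frac_up, frac_down, call |
| `phospho_protein_fc_<subtype>.tsv` | protein_id, mean_fc, best_p, n_sites |
| `multiplicity_summary.tsv` | subtype, tissue, mult_1, mult_2, mult_3plus, total_sites, n_phosphoproteins |
| `quadrants.tsv` | feature_id, fc_idc, fc_ilc, quadrant |
| `signatures.tsv` | feature_id, prot_idc, prot_ilc, phos_idc, phos_ilc, group, matches |
| `ksea_<subtype>.tsv` | kinase, m, mean_substrate_log2fc, global_mean_log2fc, global_sd_log2fc, z, p, direction, significant, kinome_group |
| `normalization_<layer>.tsv` | sample_id, offset_log2, n_features_used |

See `docs/methods.md` for the model, parameter defaults and the design
decisions behind them.
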
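"""Three-step systems-genetics integration of pQTLs and phenotypes.

For each (protein, trait) pair the three steps are:

1. intersection of the protein's cis-significant SNPs with the trait's
   QTL SNPs; the lead shared SNP minimises max(p_protein, p_trait);
2. biweight-midcorrelation association of strain-level protein abundance
   with the trait, passing when p < 0.05 with |r| beyond the magnitude
   filter (r <= -0.3 or r >= 0.6);
3. allelic contrast at the lead shared SNP: pooled-variance Student
   t-tests of protein abundance and of the trait between the two
   homozygous allele groups, both p < 0.05 and (optionally) direction
   concordance sign(delta_protein * delta_trait) == sign(r).

A protein passing all three steps for a trait is *prioritized* as a
candidate causal regulator; partial step patterns are reported as-is.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypePanel, RunConfig

log = logging.getLogger(__name__)

__all__ = ["shared_snps", "allelic_contrast", "integrate"]


def shared_snps(protein_snps: set[str], trait_snps: set[str],
                p_protein: pd.Series, p_trait: pd.Series):
    """Exact intersection of significant SNP id sets plus the lead SNP.

    The lead shared SNP minimises the larger of the two per-scan
    p-values; ties break on SNP id.  Returns (shared set, lead id or
    None, lead strength).
    """
    shared = set(protein_snps) & set(trait_snps)
    if not shared:
        return shared, None, np.inf
    strength = {
        s: max(float(p_protein.get(s, 1.0)), float(p_trait.get(s, 1.0)))
        for s in shared
    }
    lead = min(sorted(shared), key=lambda s: (strength[s], s))
    return shared, lead, strength[lead]


def allelic_contrast(snp_id: str, panel: GenotypePanel,
                     protein_values: pd.Series, trait_values: pd.Series,
                     min_group: int = 3) -> dict:
    """Student t contrasts between homozygous allele groups at one SNP.

    Heterozygous and missing-genotype strains are excluded; both
    homozygote groups must have at least ``min_group`` strains, otherwise
    the record is marked untestable.
    """
    g = panel.dosage[snp_id]
    rec = {"snp_id": snp_id, "testable": False,
           "n_ref": 0, "n_alt": 0,
           "protein_t": np.nan, "protein_p": np.nan,
           "trait_t": np.nan, "trait_p": np.nan}
    ref = g.index[g == 0.0]
    alt = g.index[g == 2.0]
    for name, values in (("protein", protein_values), ("trait", trait_values)):
        a = values.reindex(ref).dropna()
        b = values.reindex(alt).dropna()
        if name == "protein":
            rec["n_ref"], rec["n_alt"] = len(a), len(b)
        if len(a) < min_group or len(b) < min_group:
            return rec
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                rec[f"{name}_t"], rec[f"{name}_p"] = 0.0, 1.0
                continue
            return rec
        t, p = stats.ttest_ind(b.to_numpy(), a.to_numpy(), equal_var=True)
        rec[f"{name}_t"], rec[f"{name}_p"] = float(t), float(p)
    rec["testable"] = True
    return rec


def integrate(protein_ids, trait_id: str, *, cis_sets: dict[str, set[str]],
              trait_sets: dict[str, set[str]], protein_assoc: pd.DataFrame,
              trait_assoc: pd.DataFrame, strain_matrix: pd.DataFrame,
              traits, corr_results: pd.DataFrame, panel: GenotypePanel,
              cfg: RunConfig | None = None,
              opls_selected: dict[str, bool] | None = None) -> pd.DataFrame:
    """Evaluate the three steps for each protein against one trait.

    Inputs are the upstream artifacts: per-feature significant SNP sets
    (cis rule for proteins, q-threshold for traits), the raw association
    tables (for lead-SNP strengths), the strain-level abundance matrix,
    the trait table, and the protein-trait correlation table.  Records
    are sorted by lead shared-SNP strength (ascending).
    """
    cfg = cfg or RunConfig()
    trait_vals = traits.values[trait_id]
    strains = set(panel.strain_ids)
    bad = [s for s in strain_matrix.index if s not in strains]
    if bad:
        raise ValueError(f"strains absent from genotype panel: {bad[:5]}")

    p_by_feat = {
        fid: sub.set_index("snp_id")["p"]
        for fid, sub in protein_assoc.groupby("feature_id")
    }
    p_trait = (trait_assoc[trait_assoc["feature_id"] == trait_id]
               .set_index("snp_id")["p"])
    corr = corr_results[corr_results["feature_b"] == trait_id].set_index(
        "feature_a")

    records = []
    for pid in protein_ids:
        shared, lead, strength = shared_snps(
            cis_sets.get(pid, set()), trait_sets.get(trait_id, set()),
            p_by_feat.get(pid, pd.Series(dtype=float)), p_trait,
        )
        step1 = len(shared) > 0
        if pid in corr.index:
            r = float(corr.loc[pid, "r"])
            p_corr = float(corr.loc[pid, "p"])
            step2 = bool(corr.loc[pid, "selected"])
        else:
            r, p_corr, step2 = np.nan, np.nan, False
        step3 = False
        contrast = None
        if step1 and lead is not None:
            contrast = allelic_contrast(
                lead, panel, strain_matrix[pid], trait_vals,
                min_group=cfg.min_allele_group,
            )
            if contrast["testable"]:
                both_sig = (contrast["protein_p"] < 0.05
                            and contrast["trait_p"] < 0.05)
                if cfg.require_concordance and np.isfinite(r):
                    concordant = (np.sign(contrast["protein_t"]
                                          * contrast["trait_t"])
                                  == np.sign(r))
                else:
                    concordant = True
                step3 = bool(both_sig and concordant)
        pattern = "".join(str(i + 1) for i, s in
                          enumerate((step1, step2, step3)) if s)
        verdict = ("prioritized" if step1 and step2 and step3
                   else "partial" if pattern else "none")
        rec = {
            "protein_id": pid, "trait_id": trait_id,
            "n_shared_snps": len(shared), "lead_shared_snp": lead,
            "lead_strength": strength,
            "r": r, "corr_p": p_corr,
            "opls_selected": (opls_selected or {}).get(pid, np.nan),
            "step_pattern": pattern, "verdict": verdict,
        }
        if contrast is not None:
            rec.update({k: contrast[k] for k in
                        ("n_ref", "n_alt", "protein_t", "protein_p",
                         "trait_t", "trait_p")})
        records.append(rec)
    out = pd.DataFrame(records)
    return out.sort_values(["lead_strength", "protein_id"],
                           kind="stable").reset_index(drop=True)
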
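"""Simulate a small breeding seedling orchard with known truth.

Generates three provenances of open-pollinated families with partial selfing
(s = 0.30), bulk seed lots of unknown parentage, gene-dropped SNP genotypes
for a partially genotyped panel, and height phenotypes (decimetres) on
rectangular grids with an AR1 x AR1 spatial trend.
"""

import numpy as np

from orchardblup import SimConfig, simulate_orchard
from orchardblup.simulate import SiteLayout, SiteVariance

sites = ("ILRI", "SM", "Suba")
cfg = SimConfig(
    n_provenances=3, families_per_provenance=8, trees_per_family_per_site=8,
    n_bulk_lots=4, trees_per_bulk_lot_per_site=5, n_snps=600,
    site_layouts={s: SiteLayout(16, 15, 4) for s in sites},
    variance_truth={s: SiteVariance(2.5, 1.5, 2.0, 6.0) for s in sites},
    site_means={"ILRI": 16.0, "SM": 9.0, "Suba": 12.0},
    selfing_rate=0.30, seed=42)
data = simulate_orchard(cfg)

trial = data.trial
print(f"pedigree records:   {len(data.pedigree)} "
      f"(founders {len(data.pedigree.founders())})")
print(f"phenotyped trees:   {len(trial)} on {trial['site'].nunique()} sites")
print(f"genotyped panel:    {len(data.genotyped_ids)} trees x "
      f"{data.genotypes.n_loci} SNPs (missing "
      f"{data.genotypes.missing_mask().mean():.1%})")
selfed = data.truth.parentage["selfed"]
print(f"realized selfing:   {selfed[data.truth.parentage['site'].notna()].mean():.3f}"
      " among planted trees (truth s = 0.30)")
print(f"height by site (dm): "
      + ", ".join(f"{s}: {trial.loc[trial.site == s, 'height'].mean():.1f}"
                  for s in sites))
# The truth object carries per-tree breeding values per site, the spatial
# surfaces and the realized pedigree, so downstream estimates can be checked
# against what generated the data.
bv = data.truth.true_breeding_values
print(f"population variance of true BVs at ILRI: "
      f"{bv.loc[trial['id'], 'ILRI'].var():.2f} dm^2 "
      "(within-provenance founder variance 2.5, plus provenance drift "
      "and selfing inflation)")
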
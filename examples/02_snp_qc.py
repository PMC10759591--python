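"""SNP quality control: locus missingness, heterozygosity, individual missingness.

Loci with >= 15% missing calls or observed heterozygosity <= 0.05 are
removed, then individuals with >= 15% missing calls, in that order.
"""

from orchardblup import SimConfig, run_qc, simulate_orchard
from orchardblup.simulate import SiteLayout, SiteVariance

cfg = SimConfig(
    n_provenances=2, families_per_provenance=8, trees_per_family_per_site=8,
    n_bulk_lots=0, trees_per_bulk_lot_per_site=0, n_snps=800,
    site_layouts={"S": SiteLayout(12, 11, 2)},
    variance_truth={"S": SiteVariance()}, site_means={"S": 12.0},
    genotyped_families_fraction=1.0, genotyped_fraction=1.0,
    missing_locus_rate=0.04, bad_locus_fraction=0.08,
    low_het_locus_fraction=0.05, seed=7)
data = simulate_orchard(cfg)

filtered, report = run_qc(data.genotypes)
print(report.summary())
print(f"surviving matrix: {filtered.n_individuals} individuals x "
      f"{filtered.n_loci} loci")
# every surviving locus/individual satisfies the stated thresholds
miss = filtered.missing_mask()
print(f"max locus missingness after QC:      {miss.mean(axis=0).max():.3f}")
print(f"max individual missingness after QC: {miss.mean(axis=1).max():.3f}")
het = (filtered.calls == 1).sum(axis=0) / (~miss).sum(axis=0)
print(f"min locus heterozygosity after QC:   {het.min():.3f}")
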
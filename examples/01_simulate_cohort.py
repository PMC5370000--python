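"""Generate a small synthetic cohort and inspect its structure.

The generator emulates a colorectal case cohort: Hardy-Weinberg
genotypes, site-specific covariates, Agilent-like array signal with
per-sample scale distortions and detection dropout, a paired carcinoma
array for most cases, and planted SNP effects recorded in a truth table.
"""

from mireqtl import SimulationParams, generate_cohort

params = SimulationParams(n_samples=200, n_snps=5, n_mirnas=100,
                          master_seed=42)
cohort, truth = generate_cohort(params)

print(f"samples: {len(cohort.normal.sample_ids)} normal, "
      f"{len(cohort.carcinoma.sample_ids)} with a carcinoma pair")
print(f"genotypes: {len(cohort.genotypes.snp_ids)} SNPs, "
      f"{cohort.genotypes.calls.isna().to_numpy().mean():.1%} missing calls")
print(f"expression: {len(cohort.normal.probe_ids)} probes, "
      f"detected fraction {cohort.normal.detection.to_numpy().mean():.2f}")
print(f"planted effects: {len(truth.entries)} "
      f"(normal-tissue: {len(truth.affected_pairs('normal'))})")
for entry in truth.entries[:3]:
    print(f"  {entry.snp_id} -> {entry.mirna_id} [{entry.tissue}] "
          f"effect {entry.effect_size:+.2f} residual SD")
# Each planted entry shifts the miRNA's log2 signal for variant-group
# carriers of that SNP; the complement of the registry is the null set.
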
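"""Build a genomic relationship matrix from raw SNP genotypes.

Simulates a small panel, applies the standard marker pipeline
(5% MAF/heterozygosity/missing filters, windowed LD pruning at
r² ≤ 0.8, frequency imputation) and computes the kinship
K = (M − p)(M − p)' / Σ p(1−p) on the {1, 0.5, 0} code scale.
"""

import cgmtap

sim = cgmtap.simulate(cgmtap.SimConfig(n_varieties=50, n_markers=400,
                                       n_environments=6,
                                       class_counts=(2, 1, 2, 1)), seed=1)
raw = sim.markers
filtered = cgmtap.filter_markers(raw)
pruned = cgmtap.ld_prune(filtered)
imputed = cgmtap.impute_missing(pruned)
K = cgmtap.compute_kinship(imputed)

print(f"markers: {raw.n_markers} raw -> {filtered.n_markers} filtered "
      f"-> {pruned.n_markers} after LD pruning")
print(f"kinship: {len(K.variety_ids)} varieties, scaling b = {K.scale_b:.2f}")
print(f"mean diagonal = {K.values.diagonal().mean():.3f} "
      "(~1 for a panel in Hardy-Weinberg-like frequencies)")
print(f"off-diagonal range: [{K.values[0, 1:].min():.3f}, "
      f"{K.values[0, 1:].max():.3f}]  (relatedness of variety 1 to the rest)")
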
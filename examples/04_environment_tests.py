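"""Which environmental factors structure the community?

PERMANOVA (sequential terms), CAP/db-RDA (joint constrained inertia), and
ANOSIM on a categorical soil-type grouping, all on the same dissimilarity
matrix with seeded permutation nulls.
"""

from soilbiogeo import (SyntheticConfig, anosim, bray_curtis, cap,
                        generate_dataset, pcoa, permanova, rarefy)

cfg = SyntheticConfig(n_otus=300, n_core=25, seed=11)
landscape, table, tree, truth = generate_dataset(cfg)
d = bray_curtis(rarefy(table, seed=1))

design = landscape.env[["PRE", "pH"]]
for t in permanova(d, design, n_perm=999, seed=0):
    print(f"PERMANOVA {t.term:>4}: pseudo-F = {t.statistic:.2f}, "
          f"R^2 = {t.r_squared:.3f}, P = {t.p_value:.3f}")

ord_c, test = cap(d, design, n_perm=999, seed=0)
print(f"CAP (PRE + pH): constrained inertia fraction = {test.r_squared:.3f}, "
      f"pseudo-F = {test.statistic:.2f}, P = {test.p_value:.3f}")

# ANOSIM needs >= 2 samples per group: keep the represented texture classes
from collections import Counter
counts = Counter(landscape.soil_type)
keep = [s for s, t in zip(landscape.sample_ids, landscape.soil_type) if counts[t] >= 2]
groups = [t for t in landscape.soil_type if counts[t] >= 2]
res = anosim(d.reorder(keep), groups, n_perm=999, seed=0)
print(f"ANOSIM by soil type ({len(keep)} samples): "
      f"R = {res.statistic:.3f}, P = {res.p_value:.3f}")
print("-> climate covariates structure the community; soil texture does not")
print("   (the generator plants pH/PRE responders but no texture effect).")
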
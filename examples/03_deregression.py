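"""De-regress EBV into DRP and verify the calibration that motivates it.

Shrunken EBV regress on the true breeding value with slope equal to their
reliability; de-regressed proofs restore slope 1, which is what makes them
usable as pseudo-phenotypes in a second evaluation.
"""

import numpy as np
import pandas as pd

from onestepblend import DeregressionInput, SimConfig, deregress
from onestepblend.popsim import Pedigree, UNKNOWN, simulate_genotypes, simulate_traits

# a parentless cohort isolates the own-information part of deregression
n = 5000
ped = Pedigree(pd.DataFrame({
    "animal": [f"C{i:05d}" for i in range(n)],
    "sire": UNKNOWN, "dam": UNKNOWN, "order": range(n),
    "genotyped": True, "cohort": "ref_cow", "sex": "F",
}))
cfg = SimConfig(n_snps=300, n_qtl=100, drp_mode="deregress", seed=42)
geno = simulate_genotypes(ped, cfg)
t = simulate_traits(ped, geno, cfg).table

g = t["true_bv"].to_numpy()
print(f"slope of EBV on true BV: {np.polyfit(g, t['ebv'], 1)[0]:.3f} "
      f"(mean reliability = {t['rel_ebv'].mean():.3f})")
print(f"slope of DRP on true BV: {np.polyfit(g, t['drp'], 1)[0]:.3f} (target: 1)")

# deregression with a parent average: the PA part is removed and only the
# animal's own information is kept
inp = DeregressionInput(pd.DataFrame({
    "animal": ["example"], "ebv": [10.0], "rel_ebv": [0.9],
    "sire_ebv": [5.0], "sire_rel": [0.5], "dam_ebv": [3.0], "dam_rel": [0.3],
}))
out = deregress(inp)
print("\nsingle animal, EBV 10 with PA 4 (reliability 0.9 vs PA 0.2):")
print(f"  DRP = {out.loc[0, 'drp']:.3f}, reliability of DRP = {out.loc[0, 'rel_drp']:.3f}")
print("  (the DRP exceeds the EBV because shrinkage toward the PA is undone)")
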
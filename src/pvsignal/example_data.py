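"""Small synthetic worked examples bundled with the package.

``instrument_selection_example`` is a hand-constructed 10-SNP exposure/outcome
pair with a pairwise LD matrix that exercises every instrument-selection and
harmonization rule: the cis window, the F >= 10 filter, window-limited greedy
clumping, palindromic exclusion, and allele swap / strand flip reconciliation.
The expected survivor sets are derived by hand and frozen here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mr import GeneLocus

#: gene window for the example locus (cis region = 500,000 .. 1,600,000)
EXAMPLE_LOCUS = GeneLocus(gene="HDAC5", chrom="1", start=1_000_000, end=1_100_000)

#: survivors of select_instruments (sorted by snp id)
EXPECTED_SELECTED = ["rs1", "rs10", "rs5", "rs7", "rs9"]
#: survivors of harmonize (rs5 is palindromic and must fall out)
EXPECTED_HARMONIZED = ["rs1", "rs10", "rs7", "rs9"]
#: per-SNP drop reasons from the selection provenance trail
EXPECTED_STATUS = {
    "rs1": "kept", "rs2": "clump_drop", "rs3": "cis_fail", "rs4": "f_fail",
    "rs5": "kept", "rs6": "cis_fail", "rs7": "kept", "rs8": "clump_drop",
    "rs9": "kept", "rs10": "kept",
}
#: harmonization action and aligned outcome beta per surviving SNP
EXPECTED_ALIGNED = {
    "rs1": ("same", 0.0020),
    "rs7": ("flip", 0.0040),
    "rs9": ("swap", 0.0016),
    "rs10": ("flip_swap", 0.0036),
}


def instrument_selection_example():
    """Returns (exposure, outcome, ld_r2, locus).

    Selection walk-through: candidates inside 1:500000-1600000 with
    F = (beta/se)^2 >= 10 are clumped greedily by p-value; rs2 and rs8 fall
    to nearby stronger SNPs (r^2 0.9 / 0.5), while rs10 sits 550 kb from its
    r^2 = 0.9 partner rs7 and is kept because clumping is window-limited.
    """
    exposure = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(1, 11)],
        "chrom": "1",
        "pos": [600_000, 605_000, 300_000, 700_000, 800_000,
                1_650_000, 900_000, 905_000, 1_550_000, 1_450_000],
        "effect_allele": ["A", "C", "A", "G", "A", "T", "T", "C", "A", "G"],
        "other_allele": ["G", "T", "C", "A", "T", "C", "G", "A", "G", "T"],
        "eaf": [0.30, 0.31, 0.40, 0.20, 0.25, 0.35, 0.45, 0.28, 0.22, 0.38],
        "beta": [0.10, 0.09, 0.20, 0.02, 0.12, 0.15, 0.20, 0.08, 0.08, 0.18],
        "se": [0.02, 0.02, 0.02, 0.01, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02],
        "pval": [1e-8, 1e-6, 1e-20, 4.5e-2, 1e-9,
                 1e-12, 1e-22, 1e-5, 2e-5, 1e-15],
    })

    # outcome alleles: rs1 identical; rs7 strand-flipped (A/C vs T/G);
    # rs9 swapped (G/A vs A/G, beta sign to be restored);
    # rs10 strand-flipped AND swapped (A/C vs G/T)
    outcome = exposure[["snp", "chrom", "pos"]].copy()
    outcome["effect_allele"] = ["A", "C", "A", "G", "A", "T", "A", "C", "G", "A"]
    outcome["other_allele"] = ["G", "T", "C", "A", "T", "C", "C", "A", "A", "C"]
    outcome["eaf"] = [0.30, 0.31, 0.40, 0.20, 0.25, 0.35, 0.45, 0.28, 0.78, 0.62]
    # aligned Wald ratios of the survivors are all 0.02
    outcome["beta"] = [0.0020, 0.0018, 0.0040, 0.0004, 0.0024,
                       0.0030, 0.0040, 0.0016, -0.0016, -0.0036]
    outcome["se"] = 0.001
    outcome["pval"] = 0.01

    snps = list(exposure["snp"])
    ld = pd.DataFrame(np.eye(10), index=snps, columns=snps)
    for a, b, r2 in [("rs1", "rs2", 0.9), ("rs7", "rs8", 0.5),
                     ("rs7", "rs10", 0.9), ("rs5", "rs7", 0.0002),
                     ("rs1", "rs7", 0.0001), ("rs1", "rs5", 0.0003),
                     ("rs9", "rs10", 0.0001)]:
        ld.loc[a, b] = ld.loc[b, a] = r2

    return exposure, outcome, ld, EXAMPLE_LOCUS
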
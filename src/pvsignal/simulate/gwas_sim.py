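"""Synthetic GWAS summary statistics for two-sample MR, with a truth ledger.

Latent per-SNP instrument effects gamma_j on the exposure are drawn with a
block LD structure (Gaussian copula on genotype-score correlations); observed
exposure betas add sampling noise at ``exposure_se``.  Outcome betas follow

    beta_out_j = true_beta * gamma_j + pleiotropy_j + noise(outcome_se)

so the planted causal effect and any directional pleiotropy are exactly
recoverable from the ledger.  A configurable fraction of variants receives
palindromic (A/T or G/C) allele pairs, and outcome rows can be emitted with
swapped or strand-flipped alleles to exercise harmonization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GwasSimConfig:
    n_snp: int = 50
    gene_window: tuple = ("1", 1_000_000, 1_100_000)  # (chrom, start, end)
    true_beta: float = 0.25
    exposure_se: float = 0.01
    outcome_se: float = 0.05
    instrument_sd: float = 0.10        # sd of latent exposure effects gamma_j
    ld_blocks: list = field(default_factory=list)  # [(size, r2), ...] leading SNPs
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.0
    cis_fraction: float = 1.0          # fraction of SNPs inside the cis window
    outcome_swap_frac: float = 0.2     # outcome rows with swapped alleles
    outcome_flip_frac: float = 0.1     # outcome rows with strand-flipped alleles
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.exposure_se <= 0 or self.outcome_se <= 0:
            raise ValueError("summary-statistic standard errors must be > 0")
        for frac in (self.pleiotropy_frac, self.palindromic_fraction,
                     self.cis_fraction, self.outcome_swap_frac,
                     self.outcome_flip_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        used = sum(size for size, _ in self.ld_blocks)
        if used > self.n_snp:
            raise ValueError("LD blocks cover more SNPs than n_snp")
        for size, r2 in self.ld_blocks:
            if size < 1 or not 0.0 <= r2 < 1.0:
                raise ValueError("each LD block needs size >= 1 and r2 in [0, 1)")
        chrom, start, end = self.gene_window
        if start > end:
            raise ValueError("gene_window start must not exceed end")


def _correlation_matrix(n_snp: int, ld_blocks) -> np.ndarray:
    """Block-diagonal genotype-score correlation matrix; r = sqrt(r2)."""
    C = np.eye(n_snp)
    pos = 0
    for size, r2 in ld_blocks:
        r = np.sqrt(r2)
        block = np.full((size, size), r)
        np.fill_diagonal(block, 1.0)
        C[pos:pos + size, pos:pos + size] = block
        pos += size
    return C


def generate_gwas(config: GwasSimConfig, outdir=None):
    """Generate exposure/outcome summary TSVs, the LD r^2 matrix and ledger.

    Returns ``(exposure, outcome, ld_r2, ledger)``; when ``outdir`` is given
    also writes ``exposure.tsv``, ``outcome.tsv``, ``ld.tsv`` and
    ``truth_ledger.json``.  Same seed, same bytes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snp
    chrom, start, end = config.gene_window
    chrom = str(chrom)

    snps = [f"rs{100000 + j}" for j in range(m)]
    n_cis = int(round(config.cis_fraction * m))
    # cis SNPs uniformly inside the +/-500 kb window; the rest well outside
    lo, hi = max(0, start - 450_000), end + 450_000
    pos = np.empty(m, dtype=int)
    pos[:n_cis] = np.sort(rng.integers(lo, hi + 1, size=n_cis))
    pos[n_cis:] = rng.integers(end + 2_000_000, end + 5_000_000, size=m - n_cis)

    C = _correlation_matrix(m, config.ld_blocks)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(m))

    gamma = config.instrument_sd * (L @ rng.standard_normal(m))
    beta_exp = gamma + config.exposure_se * rng.standard_normal(m)

    pleio = np.zeros(m)
    if config.pleiotropy_frac > 0:
        which = rng.random(m) < config.pleiotropy_frac
        pleio[which] = rng.normal(config.pleiotropy_mean,
                                  max(config.pleiotropy_sd, 1e-12),
                                  size=int(which.sum()))
    beta_out = (config.true_beta * gamma + pleio
                + config.outcome_se * rng.standard_normal(m))

    palindromic = rng.random(m) < config.palindromic_fraction
    pairs = []
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(0, len(pool))])
    eaf = rng.uniform(0.05, 0.95, size=m)

    def pvals(beta, se):
        from scipy.stats import norm
        z = np.abs(beta) / se
        return np.maximum(2 * norm.sf(z), 1e-300)

    exposure = pd.DataFrame({
        "snp": snps, "chrom": chrom, "pos": pos,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": np.round(eaf, 4),
        "beta": beta_exp, "se": config.exposure_se,
        "pval": pvals(beta_exp, config.exposure_se),
    })

    swap = rng.random(m) < config.outcome_swap_frac
    flip = (~swap) & (rng.random(m) < config.outcome_flip_frac)
    out_e, out_o, out_beta, out_eaf, action = [], [], [], [], []
    for j in range(m):
        ea, oa = pairs[j]
        b, f = beta_out[j], eaf[j]
        if swap[j]:
            ea, oa, b, f = oa, ea, -b, 1 - f
            action.append("swap")
        elif flip[j]:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
            action.append("flip")
        else:
            action.append("same")
        out_e.append(ea)
        out_o.append(oa)
        out_beta.append(b)
        out_eaf.append(f)

    outcome = pd.DataFrame({
        "snp": snps, "chrom": chrom, "pos": pos,
        "effect_allele": out_e, "other_allele": out_o,
        "eaf": np.round(out_eaf, 4),
        "beta": out_beta, "se": config.outcome_se,
        "pval": pvals(np.asarray(out_beta), config.outcome_se),
    })

    ld_r2 = pd.DataFrame(C ** 2, index=snps, columns=snps)

    ledger = {
        "schema": "pvsignal-gwas-truth/1",
        "seed": config.seed,
        "config": {**asdict(config), "gene_window": list(config.gene_window)},
        "gamma": gamma.tolist(),
        "pleiotropy": pleio.tolist(),
        "palindromic": palindromic.tolist(),
        "outcome_allele_action": action,
        "snps": snps,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        exposure.to_csv(outdir / "exposure.tsv", sep="\t", index=False,
                        lineterminator="\n")
        outcome.to_csv(outdir / "outcome.tsv", sep="\t", index=False,
                       lineterminator="\n")
        ld_r2.to_csv(outdir / "ld.tsv", sep="\t", index_label="snp",
                     lineterminator="\n")
        with open(outdir / "truth_ledger.json", "w") as fh:
            json.dump(ledger, fh, indent=1, sort_keys=True)

    return exposure, outcome, ld_r2, ledger
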
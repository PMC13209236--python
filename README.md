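# pvsignal

Pharmacovigilance signal detection for FAERS-style spontaneous-report data,
with a focus on the safety profile of the four approved histone deacetylase
inhibitors (HDACi: vorinostat, romidepsin, belinostat, panobinostat). The
package is written for pharmacoepidemiologists who want a tested, scriptable
version of the standard desk workflow: ingest the quarterly ASCII extracts,
deduplicate, screen drug–event pairs with four disproportionality algorithms,
characterize onset timing, model the odds of serious outcomes, and probe
causality with drug-target Mendelian randomization — all exercisable offline
against a bundled synthetic-data generator with a truth ledger.

## What it computes

**Disproportionality.** For each drug–term pair a 2×2 contingency table
(a: drug & term, b: drug & other terms, c: other drugs & term, d: the rest;
N = a+b+c+d) feeds four algorithms:

- ROR = ad/bc, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
  flagged when a ≥ 3 and the CI lower bound > 1.
- PRR = [a/(a+b)]/[c/(c+d)] with
  χ² = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] and CI
  `exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`;
  flagged when a ≥ 3, χ² ≥ 4 and CI lower bound > 1.
- BCPNN information component IC = log₂ of the shrunken observed/expected
  ratio (closed-form Bayesian approximation); flagged when a ≥ 3 and
  IC025 > 0.
- MGPS EBGM = aN/[(a+c)(a+b)] with
  EBGM05 = `exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d))`; flagged when a > 0 and
  EBGM05 > 2.

A pair is a **signal** only when all four flags hold simultaneously — a
concordance rule that trades sensitivity for specificity. Gender contrasts
use a female-vs-male ROR per term with an uncorrected Pearson χ² test.

**Time to onset.** Days from therapy start to the event (same-day onset =
1 day) are fitted with a two-parameter Weibull by maximum likelihood; the
shape α classifies the hazard of reporting: α < 1 with its whole 95% CI
below 1 is an *early failure* curve (risk declines with time on drug),
CI above 1 is *wear-out*, a straddling CI is *random*.

**Important medical events.** A report is an IME if its outcome codes meet
{death, life-threatening, hospitalization, disability, congenital anomaly}.
Univariate and multivariate logistic regressions relate IME occurrence to
gender (reference female), age and weight, continuous and banded, with
complete-case analysis and Wald inference; separation is reported as NA.

**Drug-target MR.** cis instruments for HDAC-gene expression are selected
within ±500 kb of the locus, filtered at F = (β/se)² ≥ 10, LD-clumped
(r² < 0.001 within 500 kb, greedy by p-value), harmonized against outcome
summary statistics (palindromic SNPs dropped), and combined with IVW,
MR-Egger, weighted median, simple mode and weighted mode.

## Worked example

```python
import pvsignal as pv
from pvsignal.simulate import FaersSimConfig, generate_faers
from pvsignal.simulate.faers_sim import DrugSpec

cfg = FaersSimConfig(
    n_reports=10_000, seed=42,
    drugs=[DrugSpec("vorinostat", 0.15, {"Hypophosphataemia": 10.0},
                    tto_shape=0.70, tto_scale=60.0)])
tables, ledger = generate_faers(cfg)
reports, _ = pv.build_store(tables)
store = pv.deduplicate(reports)

meddra = pv.MeddraDict(cfg.background_pts)
screen = pv.screen_terms(store, "vorinostat", level="PT", meddra=meddra, min_a=3)
print(screen[screen.signal])

subset = pv.select_primary_suspect(store, ["vorinostat"])
fit = pv.fit_weibull(pv.extract_tto(subset, "vorinostat"), drug="vorinostat")
print(fit.summary())
```

This prints one signal row — the planted term, recovered at close to its
planted reporting-odds multiplier of 10:

```
signal: Hypophosphataemia  a=197  ROR=8.07 (6.49-10.03)  PRR=7.14  IC025=1.61  EBGM05=3.09
```

and the Weibull fit of the extracted onset sample:

```
Weibull TTO fit: vorinostat
  n                 1101
  median (IQR)      36.0 (12.0-94.0)
  min-max           1-996
  scale (beta)      63.51 (95% CI 58.41-69.06)
  shape (alpha)     0.745 (95% CI 0.712-0.779)
  failure type      early
```

The shape estimate sits close to the generator's 0.70 (day-level rounding
biases it slightly upward; see `docs/methods.md`) and the whole CI is below
1, so the onset profile is called an early-failure curve: most reports
arrive in the first weeks of therapy.

The same workflow runs from a shell via the `pvsignal` CLI
(`pvsignal all --config run.yaml --seed 1 --out results/`), which also
writes per-stage CSVs and a run manifest.

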
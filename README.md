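# vitalink

Record linkage of infant death registrations to hospital birth records,
with the full downstream infant-mortality surveillance toolkit: crude,
neonatal and post-neonatal rates, birthweight- and gestational-age-specific
rates, stratified and cause-group-specific rates, all with exact binomial
confidence intervals and small-count suppression.

## The problem

Infant mortality surveillance needs each death registration joined to the
corresponding live-birth record: birthweight- and gestational-age-specific
rates cannot be computed otherwise. Where the civil live-birth registry is
incomplete, hospital discharge abstracts can serve as the birth reference
file instead. A small share of deaths is then genuinely unlinkable — births
below the hospital database's collection thresholds (< 500 g and < 20
weeks), births out of province or outside any hospital, and live births
following late terminations — while clerical noise (missing identifiers,
date and postal-code errors) defeats naive exact joins for the rest.

`vitalink` provides three pieces:

1. **A synthetic registry generator** that emulates both files with known
   ground truth: a 2009–2011 birth reference file (live births, orphan and
   stillbirth records) and a 2010–2011 infant death registration file, with
   calibrated birthweight/gestational-age structure, per-bin mortality,
   field corruption, and the three unlinkable-death mechanisms above.
2. **A two-pass linkage engine.** A deterministic pass joins on the unique
   encoded identifier. Residual deaths go through classical
   Fellegi–Sunter probabilistic linkage on the four fields common to both
   registries — infant date of birth, place of death, infant sex, and
   residential postal code. For field $k$ at agreement level $\ell$ with
   $m_{k\ell} = P(\ell \mid \text{match})$ and
   $u_{k\ell} = P(\ell \mid \text{non-match})$, a candidate pair scores

   $$w = \sum_k \log_2 \frac{m_{k\ell(k)}}{u_{k\ell(k)}},$$

   with $m$, $u$ and the match prior $\lambda$ fitted by EM under
   conditional independence. Pairs are classified by two weight thresholds
   (posterior match probability ≥ 0.9 links, ≤ 0.1 rejects, in between is
   reported as *possible*) and assigned one-to-one greedily by descending
   weight.
3. **A rates engine** producing every surveillance table from the period
   linked file, with exact binomial CIs (mid-p by default,
   Clopper–Pearson available) and suppression of cells with ≤ 5 deaths.

## Worked example

```python
import vitalink as vl

cfg = vl.PipelineConfig.demo(scale=0.1, seed=1)   # ~42k births, 2009-2011
results = vl.run_pipeline(cfg, "out")

s = results["plf"].summary
print(s["n_linked"], "of", s["n_registered_deaths"], "deaths linked")
for name, est in results["crude"].items():
    print(name, vl.rates.format_rate(est))
print(results["evaluation"])
```

prints

```
107 of 110 deaths linked
infant 4.0 (3.3-4.8)
neonatal 3.2 (2.6-3.9)
postneonatal 0.8 (0.5-1.2)
{'precision': 1.0, 'recall': 1.0, ...}
```

i.e. at one-tenth scale the registered deaths (110) over the 27,416
live births born inside the death-registration window give a crude infant
mortality rate of 4.0 per 1000 live births (mid-p exact 95% CI 3.3–4.8),
a neonatal rate of 3.2 and a post-neonatal rate of 0.8 per 1000 neonatal
survivors; the linkage recovered the ground truth perfectly at this scale
(2.7% of deaths are unlinkable by construction). At full scale (~281k
denominator births) the same pipeline yields a crude rate of ≈ 4.7 per
1000 with ≈ 3.6% of deaths unlinked.

The same run writes `out/birthweight_rates.csv`,
`out/gestational_age_rates.csv`, `out/stratified_rates.csv`,
`out/cause_rates.csv`, `out/characteristics.csv`, a linkage report and a
checksummed manifest. Everything is deterministic given config + seed.

A command-line interface mirrors the library:

```bash
vitalink run --seed 1 --out out/              # full pipeline
vitalink simulate --config cfg.yaml --out d/  # files + ground truth only
vitalink link --deaths d/deaths.csv --reference d/reference.csv --out l/
```

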
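# pcpredox

Kinetics and electron-balance analysis of competing anaerobic redox
processes in flooded-soil microcosms.

When pentachlorophenol (PCP) is incubated anaerobically in a soil slurry
together with nitrate, iron(III) oxides and sulfate, all four oxidants
compete for the electrons supplied by a donor such as lactate.  `pcpredox`
is for biogeochemists and bioremediation researchers who run such
microcosm experiments and want to quantify that competition from
concentration time series:

* **Logistic reduction kinetics** — fit C(t) = a / (1 + b·e^(−kt)) to
  cumulative Fe(II) accumulation or sulfate/PCP decrement and report the
  derived rate statistics V_max = 0.25·a·k (maximum instantaneous rate)
  and t_Vmax = ln(b)/k (time of the inflection, where C = a/2).
* **Electron-equivalent (eeq) ledger** — a stoichiometric budget of
  electrons added with the donor (lactate: 12 eeq/mol for complete
  oxidation to CO₂) versus electrons consumed per pathway
  (Fe(III): 1, NO₃⁻: 5, SO₄²⁻: 8 eeq/mol; dechlorination: 2 eeq per
  chlorine removed), in mmol per microcosm.
* **Dechlorination pathway bookkeeping** — chlorophenol congeners as
  chlorine ring-position sets (OH at position 1; 2,6 = *ortho*,
  3,5 = *meta*, 4 = *para*), single-removal step inference, and ordering
  of observed chains by first-detection time.
* **Sequential first-order chain (Bateman) kinetics** — simulate and fit
  metabolite cascades such as PCP → 2,3,4,5-TeCP → 3,4,5-TCP → 3,5-DCP →
  3-CP with exact chlorine mass balance.
* **Synthetic microcosm generator** — complete datasets with redox-tower
  structure (nitrate gone by day 3, then Fe(III)/sulfate reduction),
  amendment-dependent inhibition of dechlorination, triplicates, noise,
  and recorded ground truth for end-to-end validation.

## Worked example

Derived statistics from published-style logistic parameters (a sulfate
reduction fit: a = 5.91 mM, b = 9.03, k = 0.21 d⁻¹):

```python
>>> from pcpredox import LogisticParams, vmax, t_vmax
>>> p = LogisticParams(a=5.91, b=9.03, k=0.21)
>>> round(vmax(p), 2), round(t_vmax(p), 2)
(0.31, 10.48)
```

i.e. sulfate reduction peaks at 0.31 mM d⁻¹ on day 10.5, when half the
reducible pool is consumed.

A full synthetic pipeline — generate a triplicate control microcosm
(150 µM PCP, 20 mM lactate, 3% measurement noise, seed 1), fit every
process, and infer the dechlorination pathway:

```python
>>> from pcpredox import MicrocosmConfig, generate_microcosm
>>> from pcpredox import io as pio
>>> ds = generate_microcosm(MicrocosmConfig(seed=1))
>>> pio.fit_table(list(ds.samples),
...     baselines={"sulfate": ds.config.total_sulfate_mM,
...                "PCP": ds.config.pcp0_uM}).round(3)
  treatment_id analyte        a        b      k    vmax  t_vmax     r2  converged
0      control     PCP  140.865  564.118  0.956  33.677   6.625  0.986       True
1      control     fe2  119.500  198.463  0.769  22.983   6.877  1.000       True
2      control sulfate    5.968    9.847  0.221   0.330  10.344  1.000       True
>>> pio.pathway_report(list(ds.samples))[0]
'PCP -> 2,3,4,5-TeCP -> 3,4,5-TCP -> 3,5-DCP -> 3-CP'
```

The fitted sulfate capacity (5.97 mM) and rate constant (0.22 d⁻¹)
recover the generator's truth (6.00 mM, 0.21 d⁻¹); the congener chain
resolves to removals at the *ortho*, *ortho*, *para* and *meta* positions,
ending at 3-chlorophenol.

The same stages are available from a shell:

```bash
pcpredox simulate --config config.txt --out data/
pcpredox fit --input data/dataset.csv --out fits.csv
pcpredox eeq --input moles.csv --donor-mm 20 --volume-l 0.015 --out ledger.csv
pcpredox pathway --input data/dataset.csv --out pathway.csv
```

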
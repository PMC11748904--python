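# cardioclock

Retrospective ¹⁴C birth dating of human cardiomyocyte renewal.

Atmospheric ¹⁴C spiked during above-ground nuclear weapons testing
(1955–1963) and has declined since; DNA records the atmospheric concentration
prevailing when it was synthesized. `cardioclock` turns a measured genomic
Δ¹⁴C of sorted cardiomyocyte nuclei into estimates of how fast a patient's
cardiomyocytes renewed — distinguishing true cell renewal from the nuclear
polyploidization and binucleation that dominate DNA synthesis in the failing
heart. It is aimed at quantitative biologists working on cell-turnover
birth dating and at modellers who need a tested reference implementation of
the underlying population-balance machinery.

## The model

The pool-average ¹⁴C fraction value C(t) = 1 + Δ¹⁴C/1000 of a constant-size
population renewing at rate r(t), whose cells carry G(t) = π(t)·ν(t)
diploid-genome units (π: nuclear genome copies per nucleus, ν: mean nuclei
per cell), obeys

```
dC/dt = k(t) · (F(t) − C(t)),     k(t) = r(t) + G′(t)/G(t),
C(birth) = F(birth),
```

where F(t) is the atmospheric fraction value. The per-genome synthesis rate
k(t) decomposes into renewal (r·G), nuclear polyploidization (π′·ν) and
binucleation (π·ν′) fluxes. Renewal rates are piecewise constant — fixed at
the healthy 0.55 %/year before disease onset, free afterwards (and,
optionally, free again after LVAD implantation) — and are inferred by MCMC
under a log-uniform prior on [10⁻⁴, 10²] %/year with a Gaussian measurement
model at the AMS accuracy (1–3 % at 2σ). See `docs/methods.md` for the full
account, including the exact segmentwise ODE solution and the identifiability
floor for very low rates.

The package also provides the surrounding arithmetic: degree of nuclear
ploidy (100 % = purely diploid, 200 % = purely tetraploid), FACS sort purity
→ DNA-mass purity (Purity_x = f_x·c_x / Σ f_i·c_i), binucleated and
mononucleated-diploid fractions, isometric log-ratio coordinates for
compositional statistics, genomic ¹⁴C age by curve inversion, and a seeded
synthetic-cohort generator with a ground-truth sidecar.

## Worked example

A nonischemic-cardiomyopathy subject born 1968, symptomatic from 2008,
transplanted 2020, measured Δ¹⁴C = 380 ‰ (2 % accuracy at 2σ), degree of
nuclear ploidy 291.7 %, binucleated fraction 0.346, dated against the bundled
stylized bomb-pulse curve:

```python
import cardioclock as cc

curve = cc.stylized_bomb_curve()
rec = cc.SampleRecord(
    sample_id="NICM_demo", group="NICM",
    birth=1968.0, onset=2008.0, collection=2020.0,
    delta14c=380.0, sigma2_rel=0.02,
    degree_of_nuclear_ploidy=291.7, binucleated_fraction=0.346,
)

est = cc.genomic_c14_age(rec.delta14c, rec.birth, rec.collection, curve)
cfg = cc.FitConfig(seed=1, n_samples=20_000, n_burn=4_000)
res = cc.fit_subject(rec, curve, cfg)
dec = cc.decompose_fitted(rec, res, at="collection", config=cfg)
```

This prints (via the obvious f-strings):

```
genomic 14C age: 41.6 y (synthesis year 1978.4, 10.4 y younger than subject)
post-onset renewal: median 0.002 %/y, 50% CI [0.0005, 0.012] %/y, acceptance 0.30, ESS 3253
renewal_fraction: median 0.001  50% CI [0.    0.003]
polyploidization_fraction: median 0.775  50% CI [0.774 0.776]
binucleation_fraction: median 0.224  50% CI [0.223 0.224]
```

Reading: the subject's genomic DNA is on average 10.4 years younger than the
subject — substantial DNA synthesis after birth — yet the fitted post-onset
*renewal* rate is tiny (median 0.002 %/year with a wide credibility
interval: rates this low sit below the measurement's identifiability floor
and the interval, not the median, is the informative summary). The
decomposition shows why: at collection, ~78 % of ongoing DNA synthesis is
nuclear polyploidization and ~22 % binucleation, with renewal contributing
almost nothing.

## Command line

```
cardioclock simulate --preset mixed_small --seed 7 --out sim/
cardioclock fit --cohort sim/cohort.csv --mode two_phase --draws --out fits/
cardioclock age --cohort sim/cohort.csv --out ages.csv
cardioclock decompose --fit fits/fit_NICM.json --draws fits/draws_NICM.csv \
    --cohort sim/cohort.csv --out decomp.csv
```

All outputs carry the seed and a config hash in a provenance header; rates
are printed in %/year everywhere.

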
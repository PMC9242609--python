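# chw-incentives

Scenario projection and reconciliation of performance-based
community-health-worker (CHW) incentive earnings.

The package models a CHW compensation scheme in which a worker serving a
catchment (default 1,000 people) claims fixed rupee incentives tied to
worker actions (counseling, home visits, recordkeeping) and household
behaviors (facility delivery, immunization, contraception). It provides:

* **catalog** — a validated 23-incentive, 5-category incentive catalog
  (JSON/CSV) plus observed per-category payment records.
* **incidence** — conversion of annual demographic rates (crude birth rate,
  population proportions) into monthly beneficiary incidence per catchment.
* **scenarios** — the projection engine: monthly earnings per incentive
  under the four perfect/actual worker × household models, with category
  subtotals, totals, catchment sweeps, and an optional "paper rounding"
  mode that reproduces published one-decimal calculation chains.
* **relaxation** — expected payments for lump-sum series incentives under
  relaxed completion thresholds (pay at ≥ k of K components) and fitting of
  the threshold that best explains an observed mean payment.
* **gaps** — decomposition of scenario totals and observed payments into
  design gap, lost opportunity, and implementation gap (overpayment), plus
  category shares.
* **synthetic_data** — a seeded generator of linked household + worker
  survey microdata and payment records with the statistical structure the
  analysis assumes (contact-conditional behaviors, series completion
  counts, strict/partial payment rules, questionnaire items).
* **survey_stats** — re-estimation of action/behavior rates from microdata
  and questionnaire descriptives (awareness, payment delays, claim
  experience) with binomial intervals.
* **cli** — a `chw-incentives` command tying the stages into a pipeline.

Bundled fixtures ship the published grand totals and the handful of
published amounts/rates verbatim; all other amounts and rates are clearly
flagged placeholders (the underlying per-incentive sources are not public).

## CLI

```bash
chw-incentives project --scenario pp                  # fixture catalog projection
chw-incentives project --scenario aa --paper-rounding
chw-incentives simulate --config gen.yaml --out microdata/
chw-incentives survey-summary --microdata microdata/
chw-incentives gaps --payments payments.csv
chw-incentives relax-fit --incentive anc_series --observed 789 --incidence 1.25
chw-incentives run --config run.yaml                  # full pipeline
```

`run` accepts a YAML config with paths to a catalog, demographic rates,
a rate CSV *or* a microdata directory (rates are then re-estimated),
observed payments, and series distributions; every omitted path falls back
to the bundled fixtures, and omitted optional inputs skip their stages.

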
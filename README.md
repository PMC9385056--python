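# aspicox

Physiologically based PK/PD simulation of low-dose aspirin's antiplatelet
effect, built around the turnover of the drug's cellular targets:
bone-marrow megakaryocytes (MKs) and the platelets they release.

Aspirin acetylates a serine in the channel of platelet cyclooxygenase-1
(COX-1) irreversibly, which is why a drug with a ~20-minute half-life can be
dosed once daily: platelets cannot resynthesise the enzyme, and activity
only returns with newly released platelets.  `aspicox` is for
pharmacologists and modellers who want to run in-silico dosing experiments
on this system — comparing od/bid/tid regimens, probing conditions with
accelerated platelet turnover (essential thrombocythemia, ET) or reduced
drug bioavailability (severe obesity), and ranking the processes that
control the response through local sensitivity analysis.

## The model in brief

* **PK** — a linear compartment system (gut depot, portal blood, systemic
  blood, tissue) with first-order absorption, hepatic extraction `k_he` and
  hydrolysis in every compartment; bioavailability `F` scales oral input.
* **PD** — an irreversible acetylation flux, bilinear in COX-1 and
  sigmoidal in aspirin concentration:
  `phi = phi_max · x · a^h / (K_a50^h + a^h)`.  MKs see the tissue
  concentration; circulating platelets a portal/systemic mixture.
* **Turnover** — MK–platelet *units* (cohorts born at time `tau_i`):
  COX-1 production with an early transcription burst, degradation in MKs,
  terminal platelet release, a platelet lifespan derived from the platelet
  half-life, and an apoptotic decline.  A birth-staggered ensemble of
  units yields the whole-body readout
  `X(t) = 100 · Σ x_P,i / Σ x_P,tot,i` (% of total platelet COX-1).
* **Biomarker** — serum thromboxane B2 (sTXB2), the measurable proxy: a
  monotone conversion that produces essentially no sTXB2 below ~20%
  unacetylated COX-1.
* **Features** — `X_ss, X_1, D_1, X_2, D, PP, T_r` (plateau, first-dose
  minimum and ratio, nadir and ratio, steady-state peak-to-peak, recovery
  time), and a 6×13 local sensitivity framework (mean / Fisher /
  infinity-norm indices plus five feature-based indices per parameter).

Model equations, parameter provenance, numerical methods and known
limitations are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
from aspicox import Regimen, simulate_regimen, extract_features
from aspicox.scenarios import healthy_scenario

scenario = healthy_scenario(n_units=500)
regimen = Regimen.from_schedule(100.0, "od", days=21)
traj = simulate_regimen(regimen, scenario)
features = extract_features(traj)
```

Running `python examples/02_regimen_features.py` (which does the above and
converts to sTXB2) prints:

```
simulated -120 .. 1008 h (500 units/cycle)
X_ss (pre-dose plateau)        :  100.0 %
X_1  (after the first dose)    :   85.9 %   D_1 = 0.86
X_2  (nadir under treatment)   :   25.6 %   D   = 0.26
PP   (steady-state oscillation):    3.7 pp
T_r  (recovery after stopping) :   13.0 days
steady-state serum TXB2        :   10.1 % of baseline
```

Reading: one 100 mg dose removes only ~14% of circulating platelet COX-1
(`D_1 = 0.86`) — most of the effect accumulates over repeated doses as the
acetylated platelet pool ages, reaching a nadir around 26% of total enzyme
and near-complete suppression of the sTXB2 biomarker.  After withdrawal,
activity recovers in ~13 days: one platelet lifespan plus the tail of MK
maturation, because only newly formed platelets carry fresh enzyme.

The other examples show a single MK–platelet unit under repeated dosing
(`01`), the 13-parameter sensitivity study (`03`), and precision dosing in
ET and obesity (`04`), each printing a short interpretation.  A thin CLI
exposes the same operations:

```sh
aspicox simulate --scenario healthy --dose 100 --schedule od --weeks 3 --out traj.csv
aspicox sensitivity --scenario ET --out indices.csv
aspicox dose-grid --scenario ET --doses 25,50,100,200 --schedules od,bid,tid --out grid.csv
aspicox fit-bioavailability --obs obs.csv --regimen "100mg od" --out fit.json
aspicox reproduce fig7 --out-dir out/
```

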
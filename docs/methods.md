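# Methods

`aspicox` simulates the antiplatelet action of low-dose aspirin as the
interplay of three physiological layers: fast whole-body aspirin
pharmacokinetics (minutes), irreversible acetylation of cyclooxygenase-1
(COX-1), and the slow turnover of the enzyme's two cellular carriers — bone
marrow megakaryocytes (MKs) and the platelets they release (days).  This
note records the model equations, the meaning and provenance of the
parameters, the numerical methods, and the design decisions taken where the
biology or the published record left the choice open.

## 1. Model structure

### 1.1 Aspirin pharmacokinetics

A linear four-state compartment system with state `(G, A_S, A_B, A_T)` —
gastrointestinal depot, portal blood, systemic blood, tissue (bone marrow)
amounts in mg:

    G'   = -ka G                                    (oral dose enters G, scaled by F)
    A_S' =  ka G + k4 A_B - (k3 + kd_S) A_S
    A_B' = (1 - k_he) k3 A_S - (k1 + k4 + kd_B) A_B + k2 A_T
    A_T' =  k1 A_B - (k2 + kd_T) A_T

Oral doses are impulses into `G`, attenuated by the systemic bioavailability
`F`; hepatic extraction removes the fraction `k_he` of the portal-to-systemic
flux; every compartment hydrolyses the drug (aspirin is an ester) at its own
`kd_*`.  Concentrations are amounts over effective distribution volumes:
portal `A_S/V_S`, systemic `A_B/V_B`, tissue `A_T/V_T`.  The hydrolysis
constant `kd_B = 2.5366 /h` is fixed so that the slowest system eigenvalue
gives the drug's well-known ~20-minute terminal half-life in systemic blood.

### 1.2 Acetylation pharmacodynamics

Aspirin inactivates COX-1 irreversibly.  The flux is bilinear in the enzyme
amount and sigmoidal in the aspirin concentration:

    phi(x, a) = phi_max * x * a^h / (K_a50^h + a^h)

The sigmoid is an *empirical* concentration-effect law for the whole
acetylation step (transport into the cell, binding, acetyl transfer), not a
binding isotherm; `h` may therefore exceed 1 substantially.  Because the
flux is proportional to the enzyme amount, the whole-body maximal
acetylation flux scales with the circulating platelet count with no extra
coupling — more platelets simply carry more COX-1.

MKs, residing in the marrow, are exposed to the tissue concentration.
Circulating platelets transit both portal and systemic blood, so their
fractional acetylation rate is the mixture

    r_P(t) = (1 - w_portal) * sigma(A_B/V_B) + w_portal * sigma(A_S/V_S)

with `sigma` the Hill factor above.  The portal pathway matters: portal
concentrations are briefly high before hepatic extraction, which keeps low
doses (25 mg) pharmacologically active even when the systemic peak stays
below `K_a50`.  Single-exposure variants of the model cannot reproduce the
published single-unit endpoint percentages and the low-dose regimen
equivalences simultaneously (see §6).

### 1.3 MK–platelet units

The cell population is a continuum of *units*: cohorts of MKs born at a
common time `tau`, plus the platelets they generate.  On the age axis
`s = t - tau`:

| stage                | ages                        | processes |
|----------------------|-----------------------------|-----------|
| maturation           | `[0, T_mat)`                | COX-1 production `p(s)` (burst `p_burst` for `s < T_burst`, then `p_ss`), degradation `kd_x_ss` |
| proliferation        | `[T_mat, L_MK)`             | terminal platelet release: transfer `k5(s) = k5_ss * u^k5_shape`, `u` the position inside the window; production continues |
| platelet plateau     | `[L_MK, T_mat + L_P)`       | constant platelet number; no synthesis, no destruction |
| apoptotic decline    | `[T_mat + L_P, span)`       | platelet number falls linearly to zero; destruction hazard `k6(s) = 1/(span - s)` |

with `L_P = 2 * t_half_P` (deterministic-lifespan reading of the platelet
half-life) and `span = L_MK + L_P + T_apop`.  The unit state is
`(x_MK, x_P)` — unacetylated COX-1 amounts in MKs and platelets — plus the
totals `(x_MK_tot, x_P_tot)` which obey the same turnover equations without
the acetylation terms:

    x_MK' = p(s) - (kd_x(s) + k5(s)) x_MK - phi_T(t) x_MK
    x_P'  = k5(s) x_MK - k6(s) x_P        - phi_P(t) x_P

Platelet release is *terminal*: the transfer window is the last
`L_MK - T_mat = 6 h` of MK life with a cubic ramp (`k5_shape = 3`),
reflecting proplatelet formation by fully mature, high-ploidy MKs.  This is
a calibration result as much as a biological statement: the published
endpoint percentages require platelets to enter circulation carrying
approximately the *final* MK acetylation state (see §6).

### 1.4 Whole-body aggregation

Units are staggered deterministically: birth times spaced `span / n_units`
from one full lifespan before the window of interest.  The readouts are

    X%(t)  = 100 * sum_i x_P,i(t) / sum_i x_P_tot,i(t)
    Xa(t)  = (platelet_count/250e3) * (N_P/3000) * sum_i x_P,i(t) / n_units

The percent readout has a drug-free plateau pinned at exactly 100 by
construction (uniform staggering makes the ensemble stationary); the
absolute amount `Xa` is the object of the sensitivity analysis — a percent
plateau carries no information about the turnover parameters that set it.

### 1.5 Serum TXB2 conversion

Serum TXB2 measures the *maximal capacity* of platelet COX-1 during ex-vivo
clotting, and that capacity is spare: sTXB2 stays near baseline until the
unacetylated fraction falls toward ~20–30% of total, then collapses.  The
conversion is the renormalised Hill sigmoid

    sTXB2(x) = 100 * g(x)/g(100),   g(x) = x^12 / (33^12 + x^12)

which yields < 0.3% of baseline at 20% COX-1 (the conversion threshold) and
> 90% above ~40% COX-1.  The curve is algebraic — no TXB2 synthesis
kinetics are modelled.

### 1.6 Response features

From a treatment trajectory: `X_ss` (mean over the last 48 h before the
first dose), `X_1` (minimum over the first dosing interval, `D_1 = X_1/X_ss`),
`X_2` (minimum over the whole treatment window, `D = X_2/X_ss`), `PP`
(max − min over the last complete dosing interval), and `T_r` (time from the
end of the last dosing interval until X re-enters the ±3% band around
`X_ss` *and stays there*; the sustained criterion prevents false recovery on
oscillation shoulders).  Time is in hours on every interface.

### 1.7 Sensitivity analysis

Normalised local sensitivities by forward finite differences with a 1%
one-at-a-time parameter increment applied at the initial time:

    S_i(t_k) = [X(t_k; 1.01 p_i) - X(t_k; p_i)] / (0.01 X(t_k))

sampled hourly over the full course (pre-dose window, three treatment
weeks, recovery); exactly two whole-body runs per parameter.  Three summary
indices per parameter — mean `S_M`, Fisher `S_F` (mean square), infinity
norm `S_N` — always satisfy `S_N >= sqrt(S_F) >= |S_M|`, and five
feature-based indices `(dF/dp)(p/F)` for `F` in {X_ss, D_1, D, PP, T_r}.
The 13 analysed parameters: `ka, k3, k_he, kd_B, kd_T` (PK),
`phi_max, K_a50, h` (PD), `L_MK, p_ss, kd_x_ss, t_half_P, platelet_count`
(turnover).  Forward (not central) differences are the default; global
methods (Sobol, Morris) are out of scope.

## 2. Numerical methods

* **PK** is solved exactly: the system is linear with impulsive input, so
  each inter-dose segment is propagated through the eigendecomposition of
  the system matrix on a fine uniform grid (36 s step).  An LSODA route
  (`solve_pk_ivp`) exists purely as an independent cross-check.
* **Units**: given the PK trajectory the unit equations are *linear* in the
  COX-1 amounts (the flux is bilinear).  The production engine
  (`solve_units_fast`) therefore uses an exponential integrator: per age
  step the homogeneous decay `exp(-(turnover + exposure increment))` is
  exact — the acetylation exposure increment is the difference of the
  precomputed cumulative integral of the Hill rate — and the
  production/transfer source enters at the step midpoint with half-step
  decay (second order).  It is vectorised over all units, which share one
  age grid; drug-free totals are computed once.  A conventional stiff ODE
  route (`solve_single_unit`, LSODA restarted at dose events and stage
  boundaries, rtol 1e-8/atol 1e-10, max step 0.2 h to resolve concentration
  pulses) is cross-checked against it to < 0.05 percentage points.
* **Aggregation** uses exact grid alignment: the aggregate step divides the
  birth spacing, so every unit's age nodes land on the global grid and no
  interpolation enters the sum.
* The apoptotic destruction hazard diverges at pool extinction; it is
  capped at 5/h, which affects only the final ~0.2 h of a unit's platelet
  pool (< 1e-3 of its COX-1 mass) and cancels exactly in all
  unacetylated/total ratios.
* Degenerate inputs: a 0 mg regimen is valid sham dosing; evaluation
  outside a unit's life support returns zero derivatives; an empty
  circulating pool or a vanishing nominal output in the sensitivity
  normalisation raise errors naming the offending time.

Default problem sizes: 5000 units/cycle for full-scale reproduction; 500
for the packaged reproduction scripts; 300–500 in the test suite.
Convergence is verified explicitly: doubling the unit count moves the
trajectory by < 0.5 pp, and halving the grid step moves features by < 0.1%.

## 3. Parameterisation

No external data ship with the package.  The healthy nominal set
(`data/healthy.yaml`) was calibrated by the package authors in two stages:

1. PK rate constants fixed to physiologically plausible values with `kd_B`
   solved so the systemic terminal half-life is exactly 20 min; volumes
   `V_B = 5 L`, `V_S = 0.75 L` (portal), `V_T` effective.
2. PD and turnover parameters (`phi_max, K_a50, h, V_T, w_portal`) fit by
   least squares to the published single-unit endpoint percentages of four
   regimens (100/200 mg od, 50/100 mg bid: MK end-of-life, platelet start,
   platelet end), with turnover timescales fixed at physiological values
   (MK lifetime 7 d, maturation 6.75 d, platelet half-life 5 d, apoptosis
   2 d) and an additional soft constraint that three 25 mg doses carry
   about the same daily acetylation exposure as two 50 mg doses in both
   exposure pathways (the regimen-equivalence property of the low-dose
   range).  The fit reproduces all twelve endpoints within 4.3 pp.

The ET scenario (`data/et.yaml`) encodes accelerated platelet turnover:
MK-stage durations halved, COX-1 production and maximal acetylation flux
increased in proportion to the platelet count (350e3/µL, a
cytoreduction-managed count, i.e. ×1.4), and platelet half-life shortened
to 36 h.  The magnitudes are this package's calibration of the reported ET
phenotype (weaker once-daily response, faster recovery) — the same
top-down strategy used for the healthy set.  The obese scenario differs
from healthy *only* in `F` (default 0.2); an optional body-size scaling of
`V_B` is deliberately not applied.  Scenario minimality is machine-checked
(`scenario_diff`).

## 4. Synthetic observations

`generate_observations` samples a simulated sTXB2 profile at arbitrary
times and applies multiplicative Gaussian noise (`value = profile·(1+eps)`,
`eps ~ N(0, sd)`, clipped at zero), reproducibly by seed.  It emulates
sparse clinical sTXB2 series (trough-timed samples during treatment plus a
few recovery points).  It does **not** emulate assay floors/ceilings,
between-visit biological drift, or non-Gaussian outliers — parameter
recovery under this generator demonstrates identifiability of the
inference machinery, not robustness to real laboratory data.  The packaged
inference experiment uses a 325 mg od course: with the spare-capacity
conversion curve, a 100 mg course at `F <= 0.4` produces no sTXB2 signal at
all, so the bioavailability would be unidentifiable by construction;
325 mg places the informative transition inside the 0.1–1.0 search grid.

## 5. Known limitations

* No plasma protein binding, salicylate metabolite kinetics, or
  inter-individual PK variability; no stochastic thrombopoiesis and no
  thrombopoietin feedback of platelet count on production.
* The platelet release window and its ramp are effective descriptions;
  intravital release dynamics are richer.
* The per-platelet exposure mixture treats the pool as well mixed on the
  pulse timescale; transit-limited heterogeneous exposure during a single
  pass is not modelled.
* The sTXB2 conversion is algebraic; serum incubation kinetics are not
  modelled.

## 6. Structural tension in the published behaviour set

Three published behaviour families constrain the blood dose-response
`H(d)` (per-dose acetylation exposure of platelets): (i) the single-unit
platelet endpoints imply `2 H(50) < H(100)` — a superlinear rise between
50 and 100 mg — and pin `H(100)` and `H(200)`; (ii) the equivalence of
50 mg bid and 25 mg tid requires near-additive potency down to 25 mg,
`3 H(25) ≈ 2 H(50)`; (iii) once-daily insufficiency in accelerated
turnover requires `H(200) < 2 H(50)`.  Since `H` is monotone,
`H(200) >= H(100) > 2 H(50)` follows from (i), contradicting (iii); any
additive exposure model with one monotone dose-response can satisfy at
most two of the three families at once.  The portal/systemic mixture
softens (ii) considerably (the portal floor keeps 25 mg active), and this
package prioritises (i) — the quantitative endpoints — and (iii), which
both hold with margin.  The strict 50 bid ≈ 25 tid equivalence at full
efficacy is *not* reproduced: at the packaged ET calibration the
steady-state sTXB2 gap between the two regimens is ~6 pp, and
calibrations that shrink the gap further do so only by making both
regimens ineffective, which is not the reported phenotype.  The
corresponding assertion in the acceptance suite is left failing rather
than weakened.
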
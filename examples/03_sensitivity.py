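"""Local sensitivity analysis of the whole-body COX-1 pattern.

Perturbs each of the 13 model parameters by 1% and summarises the effect on
the absolute unacetylated-COX-1 trajectory (mean / Fisher / infinity-norm
indices) and on the five response features.
"""
from aspicox.params import Regimen
from aspicox.scenarios import healthy_scenario
from aspicox.sensitivity import SensitivityConfig, analyze_scenario

scenario = healthy_scenario(n_units=300)
regimen = Regimen.from_schedule(100.0, "od", days=21)
res = analyze_scenario(scenario, regimen, SensitivityConfig())

print("parameter        S_M      S_F      S_N   |  X_ss     D_1     T_r")
for i, name in enumerate(res.parameters):
    feats = res.S_features
    print(f"{name:14} {res.S_M[i]:7.3f} {res.S_F[i]:8.3f} {res.S_N[i]:7.3f}  |"
          f" {feats.loc['X_ss', name]:6.2f} {feats.loc['D_1', name]:7.3f}"
          f" {feats.loc['T_r', name]:7.3f}")
print()
print("The pre-dose plateau (X_ss) responds only to COX-1 turnover parameters;")
print("the first-dose drop (D_1) is governed by the acetylation flux; the")
print("recovery time (T_r) is dominated by the platelet half-life.")
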
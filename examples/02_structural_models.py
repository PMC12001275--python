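"""Solving the two compartmental systems and checking their closed forms.

The 5FU model is a one-compartment IV infusion: at steady state the
concentration is D/(IT*CL), independent of the distribution volume.  The
sunitinib model is a five-state oral parent/metabolite system with hepatic
first pass; its gut compartment depletes as D*exp(-KA*t).
"""

import numpy as np

from mmpk import DoseEvent, Theta5FU, ThetaSunitinib, css_5fu, solve_profile
from mmpk.odes import allometric_scale, model_spec, solve_states

# ---- 5FU: 4000 mg over 24 h at CL = 223 L/h ----
theta = Theta5FU(cl=223.0, v=46.1)
regimen = [DoseEvent("p1", 0.0, 4000.0, 24.0, "iv_infusion")]
prof = solve_profile(model_spec("fu5"), theta, regimen, [24.0])
print(f"5FU at end of infusion : {prof['parent'][0]:.5f} mg/L")
print(f"closed form D/(IT*CL)  : {css_5fu(4000, 24, 223):.5f} mg/L")

# ---- sunitinib: 37.5 mg daily for 4 weeks, troughs at steady state ----
theta_s = ThetaSunitinib(ka=0.13, fm=0.21, cls=35.0, qs=7.0, clm=17.0,
                         qm=2.5, qh=80.0, v2s=1820.0, v3s=588.0,
                         v2m=730.0, v3m=1230.0)
theta_s = allometric_scale(theta_s, weight=80.0)   # flows x(w/70)^0.75, volumes x w/70
reg = [DoseEvent("p2", 24.0 * d, 37.5, 0.0, "oral") for d in range(28)]
troughs = np.array([23.5 + 24.0 * d for d in (0, 6, 13, 27)])
prof = solve_profile(model_spec("sunitinib"), theta_s, reg, troughs)
for t, cp, cm in zip(troughs, prof["parent"], prof["metab"]):
    print(f"day {t/24:5.1f}: parent {cp:6.2f} ng/mL   metabolite {cm:6.2f} ng/mL")

# gut depletion follows the analytic solution exactly
states = solve_states(theta_s, reg[:1], np.array([5.0, 10.0]))
print("gut amount at t=5,10 h:", np.round(states[:, 0], 4),
      " analytic:", np.round(37.5 * np.exp(-0.13 * np.array([5.0, 10.0])), 4))
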
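"""Score a single measurement and show the equation decomposition.

A mid-session snapshot of a fatigued athlete: moderate effort (48 % MVC),
elevated timing asymmetry (120 ms), noticeable bilateral force
dissociation (0.72), warm/humid environment, somewhat depleted cognition
(65 %) and slightly short sleep (7.0 h).
"""

from wase.scoring import RawMeasurement, score_measurement

raw = RawMeasurement(t=1800.0, E=48.0, dI=120.0, phi=0.72, e_env=0.60,
                     C=65.0, S=7.0, T=0.65)
s = score_measurement(raw)

print(f"risk-factor numerator   : {s.numerator:.4f}")
print(f"protective denominator  : {s.denominator:.4f}")
print(f"temporal multiplier     : {s.multiplier:.4f}")
print(f"pre-cap score           : {s.raw_score:.3f}")
print(f"capped WASe-inf score   : {s.score:.1f}")
print(f"risk category           : {s.category}")
print()
print("The weighted risk factors (0.468) divided by the much smaller")
print("protective product (0.1092) and amplified by the late-session")
print("temporal factor put this athlete far above the 2.0 cap: an")
print("immediate-intervention (critical) reading.")
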
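"""Where does the confused state lose stability?

Sweeps the control parameter gamma, tabulates the fixed points of the
drift field, and locates the two saddle-node folds that bound the bistable
region.  The upper fold is the tipping point: past it, no stable confused
state exists and understanding must escape to the enlightened attractor.
"""

from insightews import DriftParams, critical_gamma, fixed_points

for gamma in (0.10, 0.16, 0.22, 0.28):
    fps = fixed_points(DriftParams(gamma=gamma))
    desc = ", ".join(f"u*={p.u_star:.3f} ({p.stability})" for p in fps.interior)
    print(f"gamma={gamma:.2f}: {desc}")

lower = critical_gamma(DriftParams(gamma=0.2), branch="enlightened")
upper = critical_gamma(DriftParams(gamma=0.2), branch="confused")
print(f"\nenlightened attractor appears at  gamma = {lower.gamma_star:.4f}")
print(f"confused attractor disappears at  gamma = {upper.gamma_star:.4f}")
print("\nBetween the two folds the system is bistable; above the upper fold")
print("a session is forced through the critical transition (the insight).")
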
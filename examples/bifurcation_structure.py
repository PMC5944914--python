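"""Critical lines of the cargo-transport phase diagram.

Computes the three critical individuality values at the reference restoring
force g = 0.1 (n = 0.8): the Hopf threshold of the origin for a finite
opening width, the homoclinic threshold where ballistic escape becomes a
bounded limit cycle, and the saddle-node where that cycle collapses onto the
separatrix.  Then classifies the three published reference points.
"""

from antcargo import RescaledParams, bifurcation_summary, classify_phase

res = bifurcation_summary(n=0.8, g=0.1, k_c=1.0, eps=0.0)
print(f"homoclinic threshold  f_c2 = {res.f_c2:.4f}")
print(f"saddle-node threshold f_c3 = {res.f_c3:.4f}")
print(f"transition velocities v+/- = {res.v_plus:.4f} / {res.v_minus:.4f}")

from antcargo import hopf_threshold

for eps in (0.1, 0.01):
    f_c1 = hopf_threshold(RescaledParams(n=0.8, g=0.1, f_ind=0.2, eps=eps))
    print(f"Hopf threshold at eps={eps}: f_c1 = {f_c1:.4f}")

for f_ind in (0.18, 0.23, 0.28):
    label = classify_phase(0.1, f_ind, f_c2=res.f_c2, f_c3=res.f_c3)
    print(f"(g, f_ind) = (0.1, {f_ind}) -> {label}")

# The bistable band [f_c2, f_c3] is where convergent dwell near the opening
# coexists with relaxation oscillations along the obstacle; below f_c2 the
# oscillation is replaced by unbounded escape, above f_c3 only convergence
# remains.
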
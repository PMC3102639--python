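"""Measure one vertebra with both methods.

Builds a noiseless phantom whose posterior arch is rotated 7.9 deg to the
right and whose vertebral body carries an extra 6.1 deg of torsion, then
measures it back.
"""

from spinetorsion import PhantomParams, generate_phantom, measure_vertebra

phantom = generate_phantom(PhantomParams(theta_post_deg=7.9, tau_deg=6.1))
m = measure_vertebra(phantom)

print(f"alpha (Ho's method, posterior component): {m.alpha_deg:.1f} deg")
print(f"beta  (new method, anterior component):  {m.beta_deg:.1f} deg")
print(f"tau   (torsional deformity, beta-alpha): {m.torsion_deg:.1f} deg")
print()
print("With zero landmark noise the measurements recover the ground truth")
print("exactly: the anterior component leads the posterior by 6.1 deg toward")
print("the convex (right) side of the curve.")
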
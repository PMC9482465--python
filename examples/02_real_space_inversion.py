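"""From reciprocal space to interatomic distances.

Forms the modified molecular scattering sM(s) = s I_mol / I_atom of
gas-phase glycerol and applies the damped sine transform
f(r) = ∫ sM(s) sin(s r) exp(-k s²) ds.  Peaks of f(r) sit at interatomic
distances weighted by scattering power.
"""

import uedkit as u

glycerol = u.build_glycerol()
s = u.default_s_grid()
atomic = u.atomic_intensity(glycerol, s)
molecular = u.molecular_intensity(glycerol, s)
sm = u.modified_scattering(molecular, atomic)

dist = u.sine_transform(sm)
p1, h1 = u.find_peaks(dist, (1.0, 2.0))[0]
p2, h2 = u.find_peaks(dist, (2.0, 3.0))[0]
print(f"damping constant k = {dist.settings.k:.4f} Å² "
      f"(window = 0.1 at s_max = {dist.settings.s_max} Å⁻¹)")
print(f"f(r) peaks: {p1:.2f} Å (height {h1:.2f}) and {p2:.2f} Å (height {h2:.2f})")
print("The first peak blends the bonded C-O (1.43 Å) and C-C (1.53 Å)")
print("distances; the second is the non-bonded geminal C···O/C···C shell")
print("near 2.4 Å.")
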
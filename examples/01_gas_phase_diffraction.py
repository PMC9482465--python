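"""Gas-phase electron diffraction of a single glycerol molecule.

Builds the embedded glycerol conformer, evaluates the independent-atom
(Debye) scattering at 100 kV on s in [0, 10] Å⁻¹, and locates the two
principal molecular-interference maxima of the display curve I_total s².
"""

import uedkit as u

glycerol = u.build_glycerol()
print(f"molecule: {glycerol.name} ({glycerol.n_atoms} atoms, "
      f"{len(u.pair_distances(glycerol))} atom pairs)")
print(f"electron wavelength at 100 kV: {u.electron_wavelength(100):.5f} Å")

s = u.default_s_grid()
total = u.total_intensity(glycerol, s)
weighted = u.s2_weighted(total)

(low, low_h), = u.find_peaks(weighted, (2.5, 4.0))[:1]
(high, high_h), = u.find_peaks(weighted, (4.8, 6.6))[:1]
print(f"I*s² interference maxima: {low:.2f} Å⁻¹ and {high:.2f} Å⁻¹")
print("These two rings are the reciprocal-space fingerprint of the bonded")
print("(~1.4-1.5 Å) and geminal (~2.4 Å) interatomic distances in glycerol.")
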
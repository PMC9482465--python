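"""Sample budget of a shot-averaged diffraction image.

Laser ablation consumes a few tens of picolitres per shot; a diffraction
image averages thousands of shots.  The per-image volume is their exact
product.
"""

import uedkit as u

estimate = u.consumption(27, 2750)
print(estimate)
print("A microlitre of sample therefore supports "
      f"{int(1000 / estimate.per_image_nl)} diffraction images.")
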
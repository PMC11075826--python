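"""Derived hemodynamic variables from beat-level measurements.

Cardiac output, systemic vascular resistance, body surface area and the
handgrip target force -- the small formulas shared by the generator and
the analysis pipeline.
"""

from svagree import bsa, cardiac_output, sv_indexed, svr, target_force

sv, hr, map_ = 70.0, 60.0, 90.0  # mL, bpm, mmHg

co = cardiac_output(sv, hr)
resistance = svr(map_, co)
print(f"stroke volume {sv} mL at {hr} bpm -> cardiac output {co:.1f} L/min")
print(f"MAP {map_} mmHg / CO {co:.1f} L/min -> SVR {resistance:.1f} mmHg.min/L")
# SVR is the afterload the left ventricle pumps against; it rises under
# LBNP (baroreflex vasoconstriction) and isometric handgrip.

area = bsa(177.0, 71.0)
print(f"BSA (Du Bois) for 177 cm / 71 kg: {area:.3f} m^2")
print(f"a resting stroke volume of 81 mL indexes to "
      f"{sv_indexed(81.0, area):.1f} mL/m^2")
# BSA-indexing makes stroke volume comparable across body sizes; ~43
# mL/m^2 is a normal resting Doppler value.

force = target_force((250.0, 310.0, 290.0), fraction=0.40)
print(f"handgrip target at 40% of MVC (three attempts): {force:.1f} N")
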
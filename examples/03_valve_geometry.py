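"""Parametric aortic-root geometry: profile, annulus area, mesh export."""
import numpy as np

import mplv

geom = mplv.load_fixture("geometry")
print(f"annulus radius {geom.base_radius} mm, "
      f"sinus bulge {geom.sinus_max_radius} mm at z = {geom.sinus_max_location} mm")
print(f"annulus area {mplv.annulus_area(geom) * 1e4:.3f} cm^2 "
      "(the ejection model's maximum orifice area)")

for z in np.linspace(0, geom.sinus_height, 6):
    print(f"  z = {z:5.2f} mm  wall radius {mplv.sinus_profile(geom, z):.2f} mm")
# the revolved profile interpolates the three echo-measured radii: annulus,
# sinus-of-Valsalva maximum, commissures.

wedge = mplv.build_wedge_mesh(geom, resolution=32)
full_root = wedge.replicate(6)
print(f"wedge mesh: {len(wedge.faces)} faces over {wedge.wedge_angle:.0f} deg; "
      f"6 replicas span {full_root.wedge_angle:.0f} deg")
mplv.export_mesh(wedge, "valve_wedge.stl")
print("wrote valve_wedge.stl (one-sixth of the root, for inspection)")
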
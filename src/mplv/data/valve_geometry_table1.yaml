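# Parametric aortic valve geometry for the packaged subject, measured by
# parasternal long-axis echocardiography at peak T-wave (maximum opening).
# All lengths in millimetres.
base_radius_mm: 11.5          # Rb, radius of the annulus base
commissure_radius_mm: 11.75   # Rc, radius at the commissures
valve_height_mm: 16.1         # H
sinus_height_mm: 20.36        # Hs
leaflet_height_mm: 14.0       # Lh
leaflet_free_edge_mm: 14.95   # Lf
sinus_max_radius_mm: 16.65    # Ds, maximum sinus-of-Valsalva radius
sinus_max_location_mm: 8.30   # Zs, axial location of the sinus maximum
leaflet_thickness_mm: 0.6     # uniform leaflet thickness
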
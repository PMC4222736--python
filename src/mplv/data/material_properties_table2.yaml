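# Blood and leaflet material constants for the packaged subject model.
# Blood is incompressible and Newtonian; leaflets isotropic, homogeneous,
# linearly elastic. The elastic constants are carried as metadata only
# (no leaflet mechanics are solved by the reduced-order model).
blood_viscosity_pa_s: 3.5e-3
blood_density_kg_m3: 1056.0
leaflet_young_modulus_n_m2: 6.885e6
leaflet_poisson_ratio: 0.4999
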
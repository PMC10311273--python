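{
  "comment": "Photon mass attenuation coefficients mu/rho (cm^2/g) on keV grids, 10-150 keV, from the standard tabulated compilations. For air the mass energy-absorption coefficient mu_en/rho is included (air-kerma response). Tungsten L-edge fine structure below 12.1 keV is smoothed; the K edge at 69.525 keV is kept as a two-point jump.",
  "materials": {
    "Al": {
      "density_g_cm3": 2.699,
      "energy_keV": [10, 15, 20, 30, 40, 50, 60, 80, 100, 150],
      "mu_rho_cm2_g": [26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378]
    },
    "Cu": {
      "density_g_cm3": 8.96,
      "energy_keV": [10, 15, 20, 30, 40, 50, 60, 80, 100, 150],
      "mu_rho_cm2_g": [215.9, 74.05, 33.79, 10.92, 4.862, 2.613, 1.593, 0.763, 0.4584, 0.2217]
    },
    "W": {
      "density_g_cm3": 19.3,
      "energy_keV": [10, 10.3, 12.0, 15, 20, 30, 40, 50, 60, 69.5, 69.55, 80, 100, 150],
      "mu_rho_cm2_g": [96.9, 208.0, 147.0, 103.0, 65.73, 22.73, 10.67, 5.949, 3.713, 2.552, 11.23, 7.81, 4.438, 1.581]
    },
    "air": {
      "density_g_cm3": 0.0012048,
      "energy_keV": [10, 15, 20, 30, 40, 50, 60, 80, 100, 150],
      "mu_rho_cm2_g": [5.12, 1.614, 0.7779, 0.3538, 0.2485, 0.208, 0.1875, 0.1662, 0.1541, 0.1356],
      "mu_en_rho_cm2_g": [4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098, 0.03041, 0.02407, 0.02325, 0.02496]
    },
    "water": {
      "density_g_cm3": 1.0,
      "energy_keV": [10, 15, 20, 30, 40, 50, 60, 80, 100, 150],
      "mu_rho_cm2_g": [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505]
    }
  }
}
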
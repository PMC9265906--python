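{
  "_comment": "Relative inertial constants of the three foot segments, derived from a CT scan of one adult male foot (homogeneous density 1.1 g/cm^3). relative_mass_pct: segment mass as % of total foot mass. relative_com_pct: COM location as % of segment length from the proximal joint centre. tensor: inertia tensor about the segment COM expressed in the segment frame, normalized by mass^(5/3); units kg*m^2*kg^(-5/3). Lower triangle given; symmetric completion implied.",
  "version": 1,
  "segments": {
    "phalanx": {
      "relative_mass_pct": 14.4,
      "relative_com_pct": 43.6,
      "tensor": {
        "Ixx": 2.55e-3,
        "Iyx": -0.428e-3,
        "Iyy": 1.43e-3,
        "Izx": -0.220e-3,
        "Izy": -0.0507e-3,
        "Izz": 3.38e-3
      }
    },
    "forefoot": {
      "relative_mass_pct": 42.4,
      "relative_com_pct": 41.9,
      "tensor": {
        "Ixx": 1.40e-3,
        "Iyx": -0.000748e-3,
        "Iyy": 1.73e-3,
        "Izx": -0.0510e-3,
        "Izy": -0.117e-3,
        "Izz": 2.20e-3
      }
    },
    "hindfoot": {
      "relative_mass_pct": 43.2,
      "relative_com_pct": 55.4,
      "tensor": {
        "Ixx": 1.54e-3,
        "Iyx": 0.00986e-3,
        "Iyy": 1.84e-3,
        "Izx": -0.195e-3,
        "Izy": -0.155e-3,
        "Izz": 1.48e-3
      }
    }
  }
}
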
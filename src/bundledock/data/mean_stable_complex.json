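{
  "label": "Mean stable complex",
  "interface_asa_percent": 11.2,
  "interface_polar_pct": 32.2,
  "interface_nonpolar_pct": 39.5,
  "interface_charged_pct": 28.2,
  "hbonds_per_100A2": 1.0,
  "saltbridges_per_100A2": [2.0, 6.0],
  "surface_polar_pct": 31.9,
  "surface_nonpolar_pct": 38.0,
  "surface_charged_pct": 30.0
}
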
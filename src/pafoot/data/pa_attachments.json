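{
  "_comment": "Size-normalized plantar-aponeurosis attachment coordinates for a right foot, dimensionless (multiply by the subject's |ANKL-VMH| length). Anatomical axes: x anterior, y medial, z dorsal. Insertions (bases of proximal phalanges 1-5) are expressed in the phalanx frame (origin VMH), via points (sesamoid / metatarsal heads 2-5) in the forefoot frame (origin VMB), and the single shared origin (plantar calcaneal tuberosity) in the hindfoot frame (origin HE). Slips are numbered medial to lateral.",
  "version": 1,
  "insertions": [
    [0.110, 0.689, -0.080],
    [0.173, 0.510, -0.043],
    [0.174, 0.396, -0.054],
    [0.123, 0.291, -0.061],
    [0.084, 0.158, -0.062]
  ],
  "via_points": [
    [0.660, 0.427, -0.192],
    [0.692, 0.336, -0.059],
    [0.642, 0.244, -0.064],
    [0.578, 0.136, -0.069],
    [0.496, 0.032, -0.054]
  ],
  "origin": [0.284, 0.051, -0.107]
}
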
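# Canonical B-DNA-like helix parameters for the three-site duplex model.
# Twist/rise are textbook B-DNA values; per-class radii and offsets are
# representative coarse-grained placements (replace with values derived from
# any reference structure via derive_helix_parameters for quantitative work).
twist_deg: 34.3
rise_nm: 0.34
radius_nm:
  S1: 0.92
  P1: 0.89
  B1: 0.35
  S2: 0.92
  P2: 0.89
  B2: 0.35
theta0_deg:
  S1: 0.0
  P1: -24.0
  B1: 35.0
  S2: 154.0
  P2: 178.0
  B2: 119.0
z0_nm:
  S1: 0.0
  P1: -0.19
  B1: 0.02
  S2: 0.12
  P2: 0.31
  B2: 0.10
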
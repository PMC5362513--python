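# Polymerase fidelity profiles.
#
# reported_error_rate: vendor-reported errors per base per template doubling
#   (null when the vendor states only a bound; then reported_rate_bound is
#   the upper bound implied by the vendor claim).
# base_error_rate: rate used by the preamplification simulator before
#   locus-specific multipliers.
# locus_multipliers: dimensionless, >= 0; the per-locus effective rate is
#   base_error_rate * multiplier (1.0 where omitted).  Multipliers for the
#   synthetic study scenario are calibrated once from the observed artifact
#   fractions via the linear accumulation law f ~ cycles * e / 2 (see
#   docs/methods.md) and are not adjusted thereafter.
polymerases:
  - name: HotStarTaq
    base_error_rate: 2.0e-5
    reported_error_rate: 2.0e-5
    locus_multipliers:
      F877L: 11.0      # NGS library arm: artifact fractions ~0.2-0.3%
      T878A: 2.0
  - name: Phusion
    base_error_rate: 4.4e-7
    reported_error_rate: 4.4e-7
    locus_multipliers:
      F877L: 45.0      # ddPCR arm: artifact fractions ~0.007-0.036%
      T878A: 13.0      # ~0.004-0.011%
  - name: SuperFi
    base_error_rate: 2.0e-7
    reported_error_rate: null
    reported_rate_bound: 2.0e-7   # ">100x Taq fidelity" => <= 2e-5 / 100
    locus_multipliers:
      L702H: 0.0
      W742C: 0.0
      H875Y: 0.0
      F877L: 0.0       # no artifact observed at any locus
      T878A: 0.0
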
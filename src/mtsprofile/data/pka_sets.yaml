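# Side-chain and terminal pKa sets for protein net-charge and pI calculation.
# Keys: set name -> residue/terminus -> pKa.  Acidic groups: D, E, C, Y, cterm
# (deprotonation gives -1); basic groups: R, H, K, nterm (protonation gives +1).
# Users may add sets; select by name via ChargeModel.from_name().
bjellqvist:          # the set behind the ExPASy Compute pI/Mw tool (simplified:
  nterm: 7.50        # generic N-terminal value in place of residue-specific ones)
  cterm: 3.55
  D: 4.05
  E: 4.45
  C: 9.00
  Y: 10.00
  H: 5.98
  K: 10.00
  R: 12.00
emboss:
  nterm: 8.60
  cterm: 3.60
  D: 3.90
  E: 4.10
  C: 8.50
  Y: 10.10
  H: 6.50
  K: 10.80
  R: 12.50
lehninger:
  nterm: 9.69
  cterm: 2.34
  D: 3.65
  E: 4.25
  C: 8.30
  Y: 10.07
  H: 6.00
  K: 10.53
  R: 12.48
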
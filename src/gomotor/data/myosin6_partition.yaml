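# Domain partition for a myosin VI motor head, as residue-number ranges.
#
# NOTE: these ranges are an *interpretation*.  The published description of
# the model never prints residue ranges for the converter, the big/small
# subunits or the nucleotide motifs, and different myosin VI constructs use
# different numbering.  The values below follow common structural usage for
# myosin VI (pre-powerstroke PDB 2V26 numbering): P-loop GESGAGKT around
# 150-157, switch I around 200-210, switch II starting at the DFG-like motif
# around 388-400, converter roughly 700-790.  Adjust them to your construct
# before interpreting any results; every range is configuration, not a
# constant of the package.
#
# Each entry is a list of [first_residue, last_residue] spans (inclusive),
# optionally [chain, first, last].
partition_ranges:
  MH: [[1, 699]]
  converter: [[700, 788]]
  MH_big: [[1, 440]]
  MH_small: [[441, 699]]
  P_loop: [[150, 157]]
  switch_I: [[200, 210]]
  switch_II: [[388, 400]]
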
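# Default intermolecular RNA/RNA duplex energy parameters (kcal/mol, 37 C).
#
# "XY/ZW" denotes the helix step with top strand 5'-X Y-3' paired to bottom
# strand 3'-Z W-5' (X:Z and Y:W are the two stacked base pairs).  Missing
# entries are completed by the thermodynamic symmetry XY/ZW == WZ/YX; steps
# involving a G:U wobble that remain unspecified fall back to `gu_default`.
# Watson-Crick/Watson-Crick values follow the standard published
# nearest-neighbor set; wobble-step values are coarse placeholders and can be
# replaced by dropping in a published parameter file.
stacks:
  AA/UU: -0.93
  AU/UA: -1.10
  UA/AU: -1.33
  CU/GA: -2.08
  CA/GU: -2.11
  GU/CA: -2.24
  GA/CU: -2.35
  CG/GC: -2.36
  GG/CC: -3.26
  GC/CG: -3.42
  # wobble-containing steps (coarse)
  AG/UU: -0.55
  AU/UG: -1.36
  CG/GU: -1.41
  CU/GG: -1.53
  GA/UU: -1.27
  GG/CU: -2.11
  GG/UC: -1.80
  GU/CG: -2.15
  UG/AU: -1.00
  UU/AG: -0.76
  GG/UU: 0.47
  UG/GU: 0.30
gu_default: -0.50

# Interior-loop / bulge penalty between two helices:
#   init + ext * (L - 1), with L = max(unpaired on either strand) >= 1.
loop:
  init: 3.2
  ext: 0.6
  max_len: 10

# Per-nucleotide cost of unpaired guide (miRNA) terminal bases.
end_penalty: 0.2

# Constant duplex initiation term.
duplex_init: 0.0

# Simplified intramolecular folding model used for opening energies:
# weighted base-pair maximization with a minimum hairpin loop.
fold:
  wc: -2.0
  gu: -1.0
  min_hairpin: 3
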
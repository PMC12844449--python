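# Scaffold-specific diagnostic fragment tables.
#
# Each fragment is an intrinsic cation (acylium family): its m/z is the
# monoisotopic mass of `cation` minus one electron.  `covers` lists the
# moieties retained by the fragment; a biotransformation assigned to a
# covered moiety shifts the fragment by its composition delta.
#
# `neutral_losses` are precursor-derived fragments ([M+H - X]+) that
# retain all moieties; they shift with every modification.
indazole-ADB:
  fragments:
    - label: core_acylium            # indazole-3-carbonyl cation, m/z 145.0396
      cation: C8H5N2O
      covers: [core]
    - label: core_acylium_hydrate    # amide-retaining congener, m/z 163.0502
      cation: C8H7N2O2
      covers: [core]
    - label: core_chain_acylium      # 1-(5-fluoropentyl)indazole-3-carbonyl, m/z 233.1085
      cation: C13H14FN2O
      covers: [core, side_chain]
    - label: core_chain_acylium_hydrate     # m/z 251.1190
      cation: C13H16FN2O2
      covers: [core, side_chain]
    - label: core_chain_acylium_dehydrated  # m/z 215.0979
      cation: C13H12FN2
      covers: [core, side_chain]
indole-ADB:
  fragments:
    - label: core_acylium            # indole-3-carbonyl cation, m/z 144.0444
      cation: C9H6NO
      covers: [core]
    - label: core_acylium_hydrate    # m/z 162.0550
      cation: C9H8NO2
      covers: [core]
    - label: core_chain_acylium      # 1-(5-fluoropentyl)indole-3-carbonyl, m/z 232.1132
      cation: C14H15FNO
      covers: [core, side_chain]
    - label: core_chain_acylium_hydrate     # m/z 250.1238
      cation: C14H17FNO2
      covers: [core, side_chain]
    - label: core_chain_acylium_dehydrated  # m/z 214.1027
      cation: C14H13FN
      covers: [core, side_chain]
neutral_losses:
  - label: loss_NH3
    formula: NH3
  - label: loss_H2O
    formula: H2O
  - label: loss_CH3NO     # formamide loss from the terminal amide
    formula: CH3NO
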
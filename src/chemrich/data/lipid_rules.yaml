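# Lipid classification rules, applied in order; the first matching rule wins.
#
# Each rule:
#   name         short identifier
#   target       class label assigned on match
#   match        substructure patterns (SMARTS) that must ALL match
#   exclude      substructure patterns that must NOT match
#   min_carbons  minimum total carbon count (0 = no constraint)
#
# The categories are fatty acids, the oxygenated fatty-acid derivatives
# (hydroxy / epoxy / oxo fatty acids, i.e. oxylipins) and prostaglandins.
# Plain fatty acids require a carboxylic-acid terminus and a minimum chain
# length of 8 carbons; prostaglandins a 5-membered carbocycle bearing two
# chains plus the acid terminus.

version: 1
saturation_token: "C=C"

# Class labels eligible for the saturated / unsaturated split (a lipid class
# is split when at least three members contain a carbon-carbon double bond).
lipid_class_labels:
  - Fatty acids
  - Hydroxy fatty acids
  - Epoxy fatty acids
  - Oxo fatty acids
  - Prostaglandins
  - lysophosphatidylcholines
  - LPC
  - phosphatidylcholines
  - PC
  - phosphatidylethanolamines
  - PE
  - phosphatidylinositols
  - PI
  - triacylglycerols
  - TG
  - sphingomyelins
  - ceramides
  - cholesterol esters
  - plasmalogens
  - diacylglycerols
  - monoacylglycerols

oxylipin_targets:
  - Hydroxy fatty acids
  - Epoxy fatty acids
  - Oxo fatty acids

rules:
  - name: prostaglandin
    target: Prostaglandins
    match:
      - "[#6;!R][C;R]1[C;R]([#6;!R])[C;R][C;R][C;R]1"
      - "[CX3](=O)[OX2H1,OX1-]"
    exclude:
      - "[#7]"
      - "[#15]"
    min_carbons: 16

  - name: epoxy_fatty_acid
    target: Epoxy fatty acids
    match:
      - "C1OC1"
      - "[CX3](=O)[OX2H1,OX1-]"
    exclude:
      - "[#7]"
      - "[#15]"
      - "a"
    min_carbons: 8

  - name: hydroxy_fatty_acid
    target: Hydroxy fatty acids
    match:
      - "[CX4][OX2H]"
      - "[CX3](=O)[OX2H1,OX1-]"
    exclude:
      - "[#7]"
      - "[#15]"
      - "a"
      - "[CX4;R]"
    min_carbons: 8

  - name: oxo_fatty_acid
    target: Oxo fatty acids
    match:
      - "[#6][CX3](=O)[#6]"
      - "[CX3](=O)[OX2H1,OX1-]"
    exclude:
      - "[#7]"
      - "[#15]"
      - "a"
      - "[CX4;R]"
    min_carbons: 8

  - name: fatty_acid
    target: Fatty acids
    match:
      - "[CX3](=O)[OX2H1,OX1-]"
    exclude:
      - "[#7]"
      - "[#15]"
      - "[#16]"
      - "[R]"
      - "[CX4][OX2H]"
      - "[#6][CX3](=O)[#6]"
    min_carbons: 8
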
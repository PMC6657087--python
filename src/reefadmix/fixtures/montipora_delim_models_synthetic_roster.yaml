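# Six species-delimitation partition models for the Hawaiian Montipora
# RADseq data set, with their published log marginal-likelihood estimates
# (path sampling, SNAPP).  The model descriptions, groupings and MLE values
# are the published ones.  The sample-by-sample roster is a SYNTHETIC
# reconstruction of the stated study design (16 Montipora samples: six
# M. capitata morphs plus two pooled colour-morph libraries, two M. dilatata,
# two M. cf. turgescens, and one each of M. flabellata, M. verrilli,
# M. patula and M. incrassata; Acropora cytherea as outgroup): the published
# account does not print a per-sample table for every model.
samples:
  - Mcap1        # M. capitata morph 1, red
  - Mcap2        # M. capitata morph 2, red
  - Mcap3        # M. capitata morph 3, yellow/orange
  - Mcap4        # M. capitata morph 4, yellow/orange
  - Mcap5        # M. capitata morph 5, yellow/orange
  - Mcap6        # M. capitata morph 6, red
  - McapPoolRed     # pooled red colour-morph library
  - McapPoolYellow  # pooled yellow/orange colour-morph library
  - Mdil12       # M. dilatata
  - R6Mdil       # M. dilatata
  - R19turg      # M. cf. turgescens
  - L26turg      # M. cf. turgescens
  - Mflab        # M. flabellata
  - Mverr        # M. verrilli
  - Mpat         # M. patula
  - L27incra     # M. incrassata
  - Acyth        # Acropora cytherea, outgroup in all models

colour_morph:
  red: [Mcap1, Mcap2, Mcap6, McapPoolRed]
  yellow_orange: [Mcap3, Mcap4, Mcap5, McapPoolYellow]

models:
  - id: A
    description: current taxonomy; all conspecific samples grouped
    mle: -572.42
    partition:
      Mcap1: M_capitata
      Mcap2: M_capitata
      Mcap3: M_capitata
      Mcap4: M_capitata
      Mcap5: M_capitata
      Mcap6: M_capitata
      McapPoolRed: M_capitata
      McapPoolYellow: M_capitata
      Mdil12: M_dilatata
      R6Mdil: M_dilatata
      R19turg: M_turgescens
      L26turg: M_turgescens
      Mflab: M_flabellata
      Mverr: M_verrilli
      Mpat: M_patula
      L27incra: M_incrassata
      Acyth: Acropora_cytherea
  - id: B
    description: splits M. cf. turgescens and M. dilatata samples into different species
    mle: -318.88
    partition:
      Mcap1: M_capitata
      Mcap2: M_capitata
      Mcap3: M_capitata
      Mcap4: M_capitata
      Mcap5: M_capitata
      Mcap6: M_capitata
      McapPoolRed: M_capitata
      McapPoolYellow: M_capitata
      Mdil12: M_dilatata_Mdil12
      R6Mdil: M_dilatata_R6
      R19turg: M_turgescens_R19
      L26turg: M_turgescens_L26
      Mflab: M_flabellata
      Mverr: M_verrilli
      Mpat: M_patula
      L27incra: M_incrassata
      Acyth: Acropora_cytherea
  - id: C
    description: M. dilatata complex lumped into a single species
    mle: -721.67
    partition:
      Mcap1: M_capitata
      Mcap2: M_capitata
      Mcap3: M_capitata
      Mcap4: M_capitata
      Mcap5: M_capitata
      Mcap6: M_capitata
      McapPoolRed: M_capitata
      McapPoolYellow: M_capitata
      Mdil12: M_dilatata_complex
      R6Mdil: M_dilatata_complex
      R19turg: M_dilatata_complex
      L26turg: M_dilatata_complex
      Mflab: M_dilatata_complex
      Mverr: M_verrilli
      Mpat: M_patula
      L27incra: M_incrassata
      Acyth: Acropora_cytherea
  - id: D
    description: M. capitata grouped by colour morph (red; yellow/orange); remaining samples split
    mle: -288.39
    partition:
      Mcap1: M_capitata_red
      Mcap2: M_capitata_red
      Mcap3: M_capitata_yellow
      Mcap4: M_capitata_yellow
      Mcap5: M_capitata_yellow
      Mcap6: M_capitata_red
      McapPoolRed: M_capitata_red
      McapPoolYellow: M_capitata_yellow
      Mdil12: sp_Mdil12
      R6Mdil: sp_R6Mdil
      R19turg: sp_R19turg
      L26turg: sp_L26turg
      Mflab: M_flabellata
      Mverr: M_verrilli
      Mpat: M_patula
      L27incra: M_incrassata
      Acyth: Acropora_cytherea
  - id: E
    description: M. dilatata lumped; all remaining complex samples split
    mle: -338.36
    partition:
      Mcap1: M_capitata
      Mcap2: M_capitata
      Mcap3: M_capitata
      Mcap4: M_capitata
      Mcap5: M_capitata
      Mcap6: M_capitata
      McapPoolRed: M_capitata
      McapPoolYellow: M_capitata
      Mdil12: M_dilatata
      R6Mdil: M_dilatata
      R19turg: sp_R19turg
      L26turg: sp_L26turg
      Mflab: M_flabellata
      Mverr: M_verrilli
      Mpat: M_patula
      L27incra: M_incrassata
      Acyth: Acropora_cytherea
  - id: F
    description: M. dilatata + M. flabellata lumped; M. cf. turgescens samples split
    mle: -328.74
    partition:
      Mcap1: M_capitata
      Mcap2: M_capitata
      Mcap3: M_capitata
      Mcap4: M_capitata
      Mcap5: M_capitata
      Mcap6: M_capitata
      McapPoolRed: M_capitata
      McapPoolYellow: M_capitata
      Mdil12: M_dilatata_flabellata
      R6Mdil: M_dilatata_flabellata
      R19turg: sp_R19turg
      L26turg: sp_L26turg
      Mflab: M_dilatata_flabellata
      Mverr: M_verrilli
      Mpat: M_patula
      L27incra: M_incrassata
      Acyth: Acropora_cytherea
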
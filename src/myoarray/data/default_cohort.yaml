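# Default cohort presets: group-level summary statistics (mean, SEM; fold of
# control) for the expression of 19 energy-metabolism proteins and 3 derived
# bioenergetic ratios in muscle biopsies of control donors and eight rare
# neuromuscular disease groups, with the published group sizes.
#
# Each cell is [mean_fold, sem].
control_label: CTR
value_floor: 0.0
groups:
  CTR:
    n: 20
    control: true
    markers:
      PDH: [1.0, 0.1]
      SDH: [1.0, 0.1]
      CS: [1.0, 0.1]
      Hsp60: [1.0, 0.1]
      CPT1M: [1.0, 0.1]
      HADHA: [1.0, 0.1]
      NADHs9: [1.0, 0.1]
      COX1: [1.0, 0.1]
      aF1: [1.0, 0.1]
      bF1: [1.0, 0.1]
      IF1: [1.0, 0.1]
      SOD2: [1.0, 0.1]
      bActin: [1.0, 0.1]
      GAPDH: [1.0, 0.1]
      PK: [1.0, 0.1]
      LDHA: [1.0, 0.1]
      GPD1: [1.0, 0.1]
      PYGM: [1.0, 0.1]
      ACO1: [1.0, 0.1]
      bF1_GAPDH: [1.0, 0.1]
      BEC: [1.0, 0.1]
      bF1_LDHA: [1.0, 0.1]
  ComplexI:
    n: 12
    markers:
      PDH: [1.3, 0.1]
      SDH: [1.4, 0.1]
      CS: [1.5, 0.2]
      Hsp60: [1.3, 0.1]
      CPT1M: [0.9, 0.1]
      HADHA: [1.6, 0.2]
      NADHs9: [1.8, 0.2]
      COX1: [1.2, 0.1]
      aF1: [1.1, 0.1]
      bF1: [1.3, 0.1]
      IF1: [1.0, 0.1]
      SOD2: [0.8, 0.1]
      bActin: [1.1, 0.1]
      GAPDH: [0.6, 0.1]
      PK: [1.0, 0.1]
      LDHA: [0.7, 0.1]
      GPD1: [1.1, 0.1]
      PYGM: [1.5, 0.2]
      ACO1: [1.1, 0.1]
      bF1_GAPDH: [2.5, 0.3]
      BEC: [2.1, 0.2]
      bF1_LDHA: [2.2, 0.3]
  GlycV:
    n: 7
    markers:
      PDH: [0.6, 0.1]
      SDH: [0.9, 0.1]
      CS: [0.8, 0.1]
      Hsp60: [0.8, 0.1]
      CPT1M: [1.0, 0.1]
      HADHA: [1.1, 0.2]
      NADHs9: [1.2, 0.1]
      COX1: [0.6, 0.1]
      aF1: [0.7, 0.2]
      bF1: [0.9, 0.1]
      IF1: [0.7, 0.1]
      SOD2: [1.0, 0.1]
      bActin: [1.3, 0.2]
      GAPDH: [0.8, 0.1]
      PK: [0.8, 0.1]
      LDHA: [0.6, 0.2]
      GPD1: [0.9, 0.1]
      PYGM: [0.0, 0.0]
      ACO1: [0.9, 0.1]
      bF1_GAPDH: [1.1, 0.2]
      BEC: [1.4, 0.2]
      bF1_LDHA: [1.8, 0.5]
  DMD:
    n: 6
    markers:
      PDH: [1.3, 0.2]
      SDH: [1.4, 0.2]
      CS: [1.1, 0.3]
      Hsp60: [1.7, 0.2]
      CPT1M: [1.2, 0.2]
      HADHA: [0.7, 0.1]
      NADHs9: [0.9, 0.1]
      COX1: [1.5, 0.1]
      aF1: [1.4, 0.1]
      bF1: [1.2, 0.2]
      IF1: [1.1, 0.2]
      SOD2: [0.5, 0.1]
      bActin: [1.0, 0.1]
      GAPDH: [0.4, 0.1]
      PK: [0.8, 0.2]
      LDHA: [0.4, 0.1]
      GPD1: [0.4, 0.1]
      PYGM: [0.2, 0.1]
      ACO1: [0.8, 0.1]
      bF1_GAPDH: [3.1, 0.8]
      BEC: [1.6, 0.3]
      bF1_LDHA: [3.5, 0.6]
  BMD:
    n: 6
    markers:
      PDH: [1.3, 0.4]
      SDH: [1.1, 0.2]
      CS: [0.8, 0.1]
      Hsp60: [1.2, 0.2]
      CPT1M: [0.7, 0.0]
      HADHA: [0.7, 0.1]
      NADHs9: [0.9, 0.2]
      COX1: [1.3, 0.3]
      aF1: [1.3, 0.5]
      bF1: [1.2, 0.1]
      IF1: [1.1, 0.2]
      SOD2: [0.5, 0.1]
      bActin: [1.1, 0.3]
      GAPDH: [0.9, 0.3]
      PK: [1.0, 0.2]
      LDHA: [0.6, 0.2]
      GPD1: [0.7, 0.2]
      PYGM: [0.7, 0.3]
      ACO1: [1.1, 0.3]
      bF1_GAPDH: [2.2, 1.0]
      BEC: [1.8, 0.5]
      bF1_LDHA: [2.7, 0.8]
  Xp21:
    n: 4
    markers:
      PDH: [0.7, 0.1]
      SDH: [0.9, 0.2]
      CS: [1.4, 0.4]
      Hsp60: [0.9, 0.2]
      CPT1M: [0.9, 0.0]
      HADHA: [0.8, 0.2]
      NADHs9: [1.0, 0.2]
      COX1: [0.9, 0.1]
      aF1: [0.8, 0.1]
      bF1: [1.2, 0.3]
      IF1: [0.7, 0.1]
      SOD2: [0.7, 0.2]
      bActin: [1.0, 0.1]
      GAPDH: [0.6, 0.1]
      PK: [0.8, 0.0]
      LDHA: [0.5, 0.0]
      GPD1: [0.6, 0.1]
      PYGM: [0.7, 0.1]
      ACO1: [0.9, 0.2]
      bF1_GAPDH: [1.6, 0.4]
      BEC: [1.9, 0.2]
      bF1_LDHA: [1.9, 0.4]
  LGMD2C:
    n: 6
    markers:
      PDH: [0.8, 0.1]
      SDH: [0.6, 0.1]
      CS: [0.5, 0.2]
      Hsp60: [1.3, 0.3]
      CPT1M: [0.7, 0.2]
      HADHA: [0.8, 0.3]
      NADHs9: [0.6, 0.2]
      COX1: [0.9, 0.2]
      aF1: [1.0, 0.2]
      bF1: [0.8, 0.1]
      IF1: [0.8, 0.2]
      SOD2: [0.8, 0.3]
      bActin: [0.8, 0.2]
      GAPDH: [0.3, 0.1]
      PK: [0.7, 0.1]
      LDHA: [0.3, 0.0]
      GPD1: [0.6, 0.2]
      PYGM: [0.5, 0.1]
      ACO1: [0.7, 0.2]
      bF1_GAPDH: [2.9, 0.6]
      BEC: [2.5, 0.5]
      bF1_LDHA: [2.5, 0.5]
  NCL:
    n: 6
    markers:
      PDH: [0.7, 0.1]
      SDH: [1.0, 0.2]
      CS: [1.1, 0.3]
      Hsp60: [0.9, 0.2]
      CPT1M: [1.0, 0.1]
      HADHA: [1.1, 0.2]
      NADHs9: [1.0, 0.1]
      COX1: [0.8, 0.1]
      aF1: [1.1, 0.2]
      bF1: [0.8, 0.1]
      IF1: [0.7, 0.1]
      SOD2: [0.8, 0.1]
      bActin: [1.1, 0.1]
      GAPDH: [0.6, 0.1]
      PK: [0.6, 0.1]
      LDHA: [0.4, 0.1]
      GPD1: [0.5, 0.1]
      PYGM: [0.5, 0.1]
      ACO1: [1.0, 0.1]
      bF1_GAPDH: [1.3, 0.3]
      BEC: [1.9, 0.5]
      bF1_LDHA: [1.8, 0.3]
  ICU:
    n: 6
    markers:
      PDH: [0.6, 0.1]
      SDH: [0.8, 0.1]
      CS: [1.2, 0.1]
      Hsp60: [0.8, 0.1]
      CPT1M: [1.0, 0.1]
      HADHA: [1.4, 0.2]
      NADHs9: [1.2, 0.2]
      COX1: [0.7, 0.1]
      aF1: [0.7, 0.1]
      bF1: [1.0, 0.1]
      IF1: [0.6, 0.1]
      SOD2: [1.0, 0.1]
      bActin: [1.2, 0.2]
      GAPDH: [0.5, 0.1]
      PK: [0.7, 0.1]
      LDHA: [0.4, 0.1]
      GPD1: [0.7, 0.1]
      PYGM: [0.4, 0.1]
      ACO1: [0.7, 0.1]
      bF1_GAPDH: [1.7, 0.3]
      BEC: [2.5, 0.5]
      bF1_LDHA: [3.2, 0.7]
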
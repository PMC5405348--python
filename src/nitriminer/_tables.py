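"""Published constant tables for protein physicochemical descriptors.

Sources (values transcribed from the original publications):
- average residue masses, water mass: ExPASy ProtParam documentation
- pK sets incl. residue-specific terminal corrections: Bjellqvist et al. 1993
- DIWV dipeptide instability weights: Guruprasad, Reddy & Pandit 1990
- hydropathy: Kyte & Doolittle 1982
- aliphatic-index coefficients: Ikai 1980
- molar extinction coefficients at 280 nm: Gill & von Hippel 1989
"""

# average (isotope-abundance-weighted) residue masses, Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Bjellqvist pK values (the set used by ProtParam)
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
# residue-specific terminal corrections
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                "V": 7.44, "E": 7.7}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Ikai aliphatic-index side-chain relative-volume coefficients
ALIPHATIC_COEF_VAL = 2.9
ALIPHATIC_COEF_ILE_LEU = 3.9

# Gill-von Hippel molar extinction coefficients at 280 nm, M^-1 cm^-1
EXT_TRP = 5500
EXT_TYR = 1490
EXT_CYSTINE = 125

# Guruprasad dipeptide instability weight values: DIWV[x][y] for dipeptide xy
DIWV = {
    "A": {"A": 1, "C": 44.94, "D": -7.49, "E": 1, "F": 1, "G": 1, "H": -7.49, "I": 1, "K": 1, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 1, "R": 1, "S": 1, "T": 1, "V": 1, "W": 1, "Y": 1},
    "C": {"A": 1, "C": 1, "D": 20.26, "E": 1, "F": 1, "G": 1, "H": 33.6, "I": 1, "K": 1, "L": 20.26, "M": 33.6, "N": 1, "P": 20.26, "Q": -6.54, "R": 1, "S": 1, "T": 33.6, "V": -6.54, "W": 24.68, "Y": 1},
    "D": {"A": 1, "C": 1, "D": 1, "E": 1, "F": -6.54, "G": 1, "H": 1, "I": 1, "K": -7.49, "L": 1, "M": 1, "N": 1, "P": 1, "Q": 1, "R": -6.54, "S": 20.26, "T": -14.03, "V": 1, "W": 1, "Y": 1},
    "E": {"A": 1, "C": 44.94, "D": 20.26, "E": 33.6, "F": 1, "G": 1, "H": -6.54, "I": 20.26, "K": 1, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 20.26, "R": 1, "S": 20.26, "T": 1, "V": 1, "W": -14.03, "Y": 1},
    "F": {"A": 1, "C": 1, "D": 13.34, "E": 1, "F": 1, "G": 1, "H": 1, "I": 1, "K": -14.03, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 1, "R": 1, "S": 1, "T": 1, "V": 1, "W": 1, "Y": 33.601},
    "G": {"A": -7.49, "C": 1, "D": 1, "E": -6.54, "F": 1, "G": 13.34, "H": 1, "I": -7.49, "K": -7.49, "L": 1, "M": 1, "N": -7.49, "P": 1, "Q": 1, "R": 1, "S": 1, "T": -7.49, "V": 1, "W": 13.34, "Y": -7.49},
    "H": {"A": 1, "C": 1, "D": 1, "E": 1, "F": -9.37, "G": -9.37, "H": 1, "I": 44.94, "K": 24.68, "L": 1, "M": 1, "N": 24.68, "P": -1.88, "Q": 1, "R": 1, "S": 1, "T": -6.54, "V": 1, "W": -1.88, "Y": 44.94},
    "I": {"A": 1, "C": 1, "D": 1, "E": 44.94, "F": 1, "G": 1, "H": 13.34, "I": 1, "K": -7.49, "L": 20.26, "M": 1, "N": 1, "P": -1.88, "Q": 1, "R": 1, "S": 1, "T": 1, "V": -7.49, "W": 1, "Y": 1},
    "K": {"A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": -7.49, "H": 1, "I": -7.49, "K": 1, "L": -7.49, "M": 33.6, "N": 1, "P": -6.54, "Q": 24.64, "R": 33.6, "S": 1, "T": 1, "V": -7.49, "W": 1, "Y": 1},
    "L": {"A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1, "H": 1, "I": 1, "K": -7.49, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 33.6, "R": 20.26, "S": 1, "T": 1, "V": 1, "W": 24.68, "Y": 1},
    "M": {"A": 13.34, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1, "H": 58.28, "I": 1, "K": 1, "L": 1, "M": -1.88, "N": 1, "P": 44.94, "Q": -6.54, "R": -6.54, "S": 44.94, "T": -1.88, "V": 1, "W": 1, "Y": 24.68},
    "N": {"A": 1, "C": -1.88, "D": 1, "E": 1, "F": -14.03, "G": -14.03, "H": 1, "I": 44.94, "K": 24.68, "L": 1, "M": 1, "N": 1, "P": -1.88, "Q": -6.54, "R": 1, "S": 1, "T": -7.49, "V": 1, "W": -9.37, "Y": 1},
    "P": {"A": 20.26, "C": -6.54, "D": -6.54, "E": 18.38, "F": 20.26, "G": 1, "H": 1, "I": 1, "K": 1, "L": 1, "M": -6.54, "N": 1, "P": 20.26, "Q": 20.26, "R": -6.54, "S": 20.26, "T": 1, "V": 20.26, "W": -1.88, "Y": 1},
    "Q": {"A": 1, "C": -6.54, "D": 20.26, "E": 20.26, "F": -6.54, "G": 1, "H": 1, "I": 1, "K": 1, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 20.26, "R": 1, "S": 44.94, "T": 1, "V": -6.54, "W": 1, "Y": -6.54},
    "R": {"A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": -7.49, "H": 20.26, "I": 1, "K": 1, "L": 1, "M": 1, "N": 13.34, "P": 20.26, "Q": 20.26, "R": 58.28, "S": 44.94, "T": 1, "V": 1, "W": 58.28, "Y": -6.54},
    "S": {"A": 1, "C": 33.6, "D": 1, "E": 20.26, "F": 1, "G": 1, "H": 1, "I": 1, "K": 1, "L": 1, "M": 1, "N": 1, "P": 44.94, "Q": 20.26, "R": 20.26, "S": 20.26, "T": 1, "V": 1, "W": 1, "Y": 1},
    "T": {"A": 1, "C": 1, "D": 1, "E": 20.26, "F": 13.34, "G": -7.49, "H": 1, "I": 1, "K": 1, "L": 1, "M": 1, "N": -14.03, "P": 1, "Q": -6.54, "R": 1, "S": 1, "T": 1, "V": 1, "W": -14.03, "Y": 1},
    "V": {"A": 1, "C": 1, "D": -14.03, "E": 1, "F": 1, "G": -7.49, "H": 1, "I": 1, "K": -1.88, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 1, "R": 1, "S": 1, "T": -7.49, "V": 1, "W": 1, "Y": -6.54},
    "W": {"A": -14.03, "C": 1, "D": 1, "E": 1, "F": 1, "G": -9.37, "H": 24.68, "I": 1, "K": 1, "L": 13.34, "M": 24.68, "N": 13.34, "P": 1, "Q": 1, "R": 1, "S": 1, "T": -14.03, "V": -7.49, "W": 1, "Y": 1},
    "Y": {"A": 24.68, "C": 1, "D": 24.68, "E": -6.54, "F": 1, "G": -7.49, "H": 13.34, "I": 1, "K": 1, "L": 1, "M": 44.94, "N": 1, "P": 13.34, "Q": 1, "R": -15.91, "S": 1, "T": -7.49, "V": 1, "W": -9.37, "Y": 13.34},
}
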
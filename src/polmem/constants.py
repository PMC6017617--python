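"""Physical constants and unit conversions.

Internal units are Å (length), e (charge), e·Å (dipole), e·Å² (quadrupole)
and kcal/mol (energy).  Conversions to Debye and Volt happen only at I/O
and reporting boundaries.
"""

#: Coulomb's constant in kcal·Å/(mol·e²).
COULOMB = 332.0637

#: 1 e·Å expressed in Debye.
DEBYE_PER_EA = 4.803205

#: 1 kcal/(mol·e) expressed in Volt.
VOLT_PER_KCAL_MOL_E = 0.0433641

#: Default volume of one water molecule, Å³, used for volume-per-lipid.
WATER_VOLUME = 30.53

#: Element symbol -> atomic number, for the elements occurring in lipids,
#: water and counter-ions.
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12,
    "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20,
}

SYMBOLS = {z: s for s, z in ATOMIC_NUMBERS.items()}
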
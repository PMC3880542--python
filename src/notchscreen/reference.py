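"""Published reference values for the chick DAPT (Notch-inhibition) screen.

Fold changes are signed in the GeneSpring convention: a ratio r (treated over
control) is reported as r when r >= 1 and as -1/r otherwise, so magnitudes are
always >= 1 and the sign gives the direction of change in the DAPT-treated
forebrain.
"""

from __future__ import annotations

# Notch signalling pathway components and their measured fold change after
# 16 h of gamma-secretase inhibition (DAPT) in the chick prosencephalon.
NOTCH_PATHWAY_FC: dict[str, float] = {
    "Hes5": -56.83,
    "Hey1": -2.89,
    "Nrarp": -2.02,
    "Jag1": -1.58,
    "Numb": -1.49,
    "Lfng": -1.46,
    "Notch1": -1.31,
    "Notch2": -1.30,
    "Aph1a": 1.34,
    "Dll1": 2.26,
    "Mfng": 3.15,
}

# The 23 upregulated genes of the enriched "nervous system development" GO
# term that were followed up as candidate Notch/proneural targets.
NSD_UP_FC: dict[str, float] = {
    "Neurog1": 8.85,
    "Nhlh2": 4.18,
    "Nefm": 4.05,
    "Tagln3": 3.69,
    "Nhlh1": 3.47,
    "Stmn2": 2.49,
    "Nr5a1": 1.87,
    "Nrg1": 1.77,
    "Chga": 1.74,
    "Sim1": 1.74,
    "Bsx": 1.68,
    "Ascl1": 1.67,
    "Nr5a2": 1.59,
    "Gap43": 1.57,
    "Neurog2": 1.57,
    "Sox14": 1.51,
    "Robo2": 1.46,
    "Cntn2": 1.39,
    "Slit1": 1.37,
    "Hes6": 1.36,
    "Bdnf": 1.34,
    "Foxn4": 1.31,
    "Chrdl1": 1.30,
}

#: All published fold changes (pathway components + nervous-system-development
#: block); the default planted effect sizes of the synthetic generator.
ALL_REFERENCE_FC: dict[str, float] = {**NOTCH_PATHWAY_FC, **NSD_UP_FC}

#: GO identifier of "nervous system development", the term enriched among
#: upregulated genes in the screen.
NSD_TERM = "GO:0007399"

# bHLH binding-site signatures used in the promoter scan.  EBOX/NBOX are the
# classical degenerate activator (ASCL1-type) and repressor (HES/HEY-type)
# sites; MHAM and MNAM are the strict 7-mer antagonist signatures
# (ASCL1/HEY1 and ASCL1/NHLH1 respectively) that give the scan its
# stringency.
MOTIFS: dict[str, str] = {
    "EBOX": "CANNTG",
    "NBOX": "CACNAG",
    "MHAM": "CACCTGC",
    "MNAM": "GCAGCTG",
}

#: Species panel used for the cross-species conservation fixture
#: (mammals + bird, mirroring the mammal/bird comparative scan).
DEFAULT_SPECIES: tuple[str, ...] = ("human", "mouse", "rat", "chick")

# Conserved motif placements used as ground truth by the synthetic ortholog
# promoter generator: MHAM in the Hes5/Dll1/Chga/Chrdl1 proximal promoters,
# MNAM in Robo2/Tagln3.  Offsets are TSS-relative (+1 convention, negative =
# upstream); exact offsets are fixture choices within the proximal window.
CONSERVED_PROMOTER_MOTIFS: dict[tuple[str, str], int] = {
    ("Hes5", "MHAM"): -85,
    ("Dll1", "MHAM"): -230,
    ("Chga", "MHAM"): -120,
    ("Chrdl1", "MHAM"): -60,
    ("Robo2", "MNAM"): -150,
    ("Tagln3", "MNAM"): -320,
}

# Static lateral-inhibition interaction model: DLL1 activates NOTCH in the
# neighbouring cell; NOTCH induces the HES5/HEY1 repressors; these repress
# ASCL1; ASCL1 activates DLL1, NHLH1 and the downstream neuronal targets.
REGULATORY_EDGES: list[tuple[str, str, str]] = [
    ("DLL1", "NOTCH", "activates"),
    ("NOTCH", "HES5", "activates"),
    ("NOTCH", "HEY1", "activates"),
    ("HES5", "ASCL1", "represses"),
    ("HEY1", "ASCL1", "represses"),
    ("ASCL1", "DLL1", "activates"),
    ("ASCL1", "NHLH1", "activates"),
    ("ASCL1", "TAGLN3", "activates"),
    ("ASCL1", "CHGA", "activates"),
    ("ASCL1", "CHRDL1", "activates"),
    ("ASCL1", "ROBO2", "activates"),
    ("NHLH1", "TAGLN3", "activates"),
]

#: Direction of change expected for each gene when Notch signalling is
#: blocked, taken from the published screen (sign of the reference FC).
EXPECTED_DIRECTION: dict[str, str] = {
    gene: ("up" if fc > 0 else "down") for gene, fc in ALL_REFERENCE_FC.items()
}
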
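"""Physical constants, idealized builder geometry, and default parameter sets.

Everything tunable-by-convention lives here so that the rest of the package
never hard-codes a number twice.
"""

from __future__ import annotations

# Boltzmann constant in kcal/(mol K)
KB_KCAL_MOL_K = 0.0019872041

# ---------------------------------------------------------------------------
# Idealized internal-coordinate geometry for the peptide builder (Å, degrees).
# These are conventional small-molecule values; the builder only promises
# self-consistency (measured dihedrals reproduce the requested ones), not
# agreement with any particular crystallographic survey.
# ---------------------------------------------------------------------------
BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("N", "H"): 1.010,
    ("CA", "HA"): 1.090,
    ("CA", "CB"): 1.530,
    ("C", "CH3"): 1.508,   # ACE methyl
    ("N", "CH3"): 1.458,   # NME methyl
    ("CB", "XIN"): 3.850,  # TRP indole-centroid pseudo-atom
}

BOND_ANGLES = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 116.6,
    ("C", "N", "CA"): 121.9,
    ("CA", "C", "O"): 120.4,
    ("C", "N", "H"): 119.5,
    ("CA", "N", "H"): 119.5,
    ("N", "CA", "HA"): 109.5,
    ("N", "CA", "CB"): 110.5,
    ("N", "C", "O"): 122.9,
    ("N", "C", "CH3"): 116.6,
    ("C", "N", "CH3"): 121.9,
    ("CA", "CB", "XIN"): 114.0,
}

# Improper dihedrals (degrees) used to place CA substituents, measured as
# C(i)-N(i)-CA(i)-X about the N-CA axis.  Values keep HA/CB staggered with
# respect to the carbonyl carbon and give a consistent (L-like) handedness.
CB_IMPROPER_DEG = -122.5
HA_IMPROPER_DEG = 118.0
# TRP indole centroid pseudo-torsion N-CA-CB-XIN (chi1-like), degrees
XIN_TORSION_DEG = -65.0

OMEGA_TRANS_DEG = 180.0

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
CAP_RESIDUES = {"ACE", "NME"}

# ---------------------------------------------------------------------------
# Replica-exchange temperature ladders (K) shipped as named presets.
# ---------------------------------------------------------------------------
TEMPERATURE_LADDERS = {
    "2i9m": (267.0, 283.0, 300.0, 328.0, 353.0, 380.0, 409.0,
             439.0, 471.0, 506.0, 542.0, 577.0),
    "trpzip2": (255.00, 277.09, 300.63, 325.74, 352.50, 381.04,
                411.51, 443.96, 478.65, 515.62, 555.04, 597.08),
}

# ---------------------------------------------------------------------------
# Hydrogen-bond detection defaults (configurable at every call site).
# ---------------------------------------------------------------------------
DEFAULT_HBOND_DISTANCE_A = 3.5   # N...O heavy-atom cutoff, Å
DEFAULT_HBOND_ANGLE_DEG = 120.0  # N-H...O angle at the hydrogen, degrees
DEFAULT_HBOND_MIN_SEQ_SEP = 2    # |residue i - residue j| >= 2

# Validity range of the exponential polarization model, Å.
POLARIZATION_D_MIN_A = 2.5
POLARIZATION_D_MAX_A = 6.5

# Placeholder amplitudes/decays for the Δq = a·exp(−b·d) model.  These are
# NOT published values — the fitted parameters are configuration inputs and
# a fitting utility is provided; these defaults merely give the model a
# physically plausible shape for demonstrations.
PLACEHOLDER_POLARIZATION = {
    "a_N": 0.40, "b_N": 1.00,   # e, 1/Å
    "a_O": -0.30, "b_O": 0.90,
}

# Generic AMBER-style backbone amide partial charges (e) used as default
# base charges by the CLI `polarize` command; all other atoms default to 0.
DEFAULT_BACKBONE_CHARGES = {"N": -0.4157, "H": 0.2719, "C": 0.5973, "O": -0.5679}

# ---------------------------------------------------------------------------
# Default Ramachandran regions, ordered; first match wins, "other" is the
# fallback.  Rectangles are (phi_min, phi_max, psi_min, psi_max) in degrees.
# Boundaries are conventional stand-ins and fully configurable.
# ---------------------------------------------------------------------------
DEFAULT_RAMA_REGIONS = (
    ("alpha", ((-100.0, -30.0, -67.0, -7.0),)),
    ("ppii", ((-110.0, -50.0, 120.0, 180.0),)),
    ("beta", ((-180.0, -90.0, 90.0, 180.0), (-180.0, -90.0, -180.0, -150.0))),
)

# Tightened helical box, first-match shadowing alpha when used: swap it in
# (e.g. RamaClassifier(STRICT_RAMA_REGIONS)) to split alpha populations into
# strict and loose parts.
STRICT_RAMA_REGIONS = (
    ("alpha_strict", ((-90.0, -40.0, -57.0, -17.0),)),
) + DEFAULT_RAMA_REGIONS

# Conventional HN-HA three-bond Karplus coefficients (Hz) with θ = φ − 60°.
# A widely used literature parameterization; override to match any specific
# published set.
DEFAULT_KARPLUS = {"A": 7.09, "B": -1.42, "C": 1.55, "phase_deg": 60.0}

# Trpzip2-style stacking pairs (1-based residue indices) as quoted defaults;
# overridable because the conventional native partners differ.
DEFAULT_STACKING_PAIRS = ((2, 11), (4, 11))
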
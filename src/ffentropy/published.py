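"""Reported benchmark values used as inputs by the validation report.

These are published room-temperature (300 K) results from microsecond
explicit-solvent MD of seven folded globular proteins (130-266 residues)
and of the TSR4 domain (PDB 1vex), for five protein/water force-field
combinations.  They serve two purposes: reproducing the benchmark table
arithmetic (row averages) and calibrating the chain-length-dependent
structural similarity/dissimilarity thresholds.
"""

# Characteristic nonbonded distance a (Angstrom) used in the Lindemann
# ratio dL = <RMSF>/a for proteins; average over prior protein work.
LINDEMANN_A = 4.375

# Experimental room-temperature Lindemann band for folded globular
# proteins in water (inelastic neutron scattering); report annotation.
LINDEMANN_EXPERIMENTAL_300K = (0.15, 0.16)

FOLDED_PROTEINS = ("1arb", "1b6b", "1bsg", "1rii", "2xr6", "4r3f", "4xq4")

# Per-protein Lindemann values at 300 K (a = 4.375 A, <RMSF> over all
# residues), one row per force-field combination.
LINDEMANN_FOLDED_300K = {
    "ff99sb/TIP3P":    {"1arb": 0.10, "1b6b": 0.14, "1bsg": 0.14,
                        "1rii": 0.13, "2xr6": 0.11, "4r3f": 0.11, "4xq4": 0.12},
    "ff99sb/TIP4P-Ew": {"1arb": 0.10, "1b6b": 0.13, "1bsg": 0.12,
                        "1rii": 0.12, "2xr6": 0.11, "4r3f": 0.12, "4xq4": 0.10},
    "C36m/TIP3P":      {"1arb": 0.11, "1b6b": 0.14, "1bsg": 0.11,
                        "1rii": 0.12, "2xr6": 0.11, "4r3f": 0.12, "4xq4": 0.14},
    "C36m/TIP3Pm":     {"1arb": 0.12, "1b6b": 0.18, "1bsg": 0.11,
                        "1rii": 0.13, "2xr6": 0.14, "4r3f": 0.12, "4xq4": 0.12},
    "AmPro13/AmW03":   {"1arb": 0.13, "1b6b": 0.16, "1bsg": 0.18,
                        "1rii": 0.22, "2xr6": 0.13, "4r3f": 0.16, "4xq4": 0.17},
}

# Printed per-row averages (2 d.p.) of the table above.
LINDEMANN_FOLDED_AVERAGE = {
    "ff99sb/TIP3P": 0.12,
    "ff99sb/TIP4P-Ew": 0.11,
    "C36m/TIP3P": 0.12,
    "C36m/TIP3Pm": 0.13,
    "AmPro13/AmW03": 0.16,
}

# TSR4 domain (1vex) fluctuation benchmark at 300 K:
# mean RMSD to the starting structure (A) and Lindemann values over the
# beta-sheet core, the surface (complement), and all residues.
TSR4_FLUCTUATIONS_300K = {
    "ff99sb/TIP3P":    {"rmsd": 3.8, "core": 0.16, "surf": 0.18, "total": 0.17},
    "ff99sb/TIP4P-Ew": {"rmsd": 3.5, "core": 0.16, "surf": 0.20, "total": 0.18},
    "C36m/TIP3P":      {"rmsd": 3.1, "core": 0.17, "surf": 0.23, "total": 0.20},
    "C36m/TIP3Pm":     {"rmsd": 3.0, "core": 0.18, "surf": 0.24, "total": 0.21},
    "AmPro13/AmW03":   {"rmsd": 5.5, "core": 0.20, "surf": 0.29, "total": 0.25},
}

# Residue count of the modeled TSR4 construct (a single thrombospondin
# type-1 repeat, PDB 1vex) used to calibrate the similarity thresholds.
TSR4_N_RESIDUES = 55

# Similarity / dissimilarity thresholds reported for the TSR4 chain
# length; anchor points for the D0 power-law calibration.
TSR4_D0_SIM = 1.34
TSR4_D0_DIS = 4.49
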
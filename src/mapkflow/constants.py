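"""Model constants for the stress-MAPK driver network.

All doses are fractions of the maximal inhibitor dose on [0, 1]; all flows
are fractions of the total stress input signal Sigma = 1.
"""

# Dose-response constants K_i of the hyperbolic inhibition model
# phi(x) = 1 / (1 + K_i x), one per targeted kinase node.
K_P38 = 2.0        # p38i (SB203580), target node 8
K_MEK = 0.4        # MEKi (trametinib), target node 3
K_JNK = 0.475628   # JNKi (SP600125), target node 6; drives Y6(x) = Y6(0)/(1+K3 x)
K_MLK = 0.1        # MLKi (URMC-099), target node 5

# Hill constants of the crosstalk-redirection model for JNK inhibition:
# the MLK->p38 and TAOK->p38 capacities open up as JNK activity falls,
# A3 = 1/(1+(gamma3*Y6)^4), A4 = 1/(1+(gamma4*Y6)^4).
GAMMA3 = 1.520908
GAMMA4 = 1.435780

# Repression-strength constants of the ERK (node 4) repression terms.
# Node-4 activity is held constant in this model (TAOK represses it
# maximally under saturating stress), so these are stored but unused.
GAMMA1 = None
GAMMA2 = None

# Split fractions of topology N1.  Only alpha1 carries a measured value;
# the rest are package defaults (see docs/methods.md).
ALPHA1 = 0.2
DEFAULT_SPLITS = {
    "alpha1": 0.2,
    "alpha2": 0.2,
    "alpha3": 0.5,
    "alpha4": 0.5,
    "alpha5": 0.5,
    "alpha6": 0.5,
}

# Fraction of the JNK-inhibition surplus that node 8 (p38) cannot absorb
# and that is exported toward compensatory networks.
JNK_EXPORT_FRACTION = 1.0 / 3.0

# Default activation threshold of a compensatory kinase network,
# as a fraction of the total stress input.
DEFAULT_THETA = 0.3

# Dose cap of the low-dose four-drug regimen (4D-MAPKi).
FOUR_D_DOSE_CAP = 0.3
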
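"""Physical constants and spin parameters used across the relaxation modules.

All values in SI units unless noted. The NH bond length and the 15N CSA are
the standard literature values used by common model-free packages.
"""

# fundamental
MU0_OVER_4PI = 1.0e-7  # T m / A
HBAR = 1.054571817e-34  # J s

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7116e7  # 15N
GAMMA_C = 6.728284e7  # 13C

# backbone amide parameters
R_NH = 1.02e-10  # m, effective N-H bond length
CSA_N = -172.0e-6  # 15N chemical shift anisotropy (axially symmetric)
THETA_DD_CSA_DEG = 17.0  # angle between the N-H vector and the CSA unique axis

# intra-methyl 1H-1H geometry (for SQ/TQ cross-correlated relaxation)
R_HH_METHYL = 1.813e-10  # m, distance between methyl proton pairs
THETA_AXIS_HH_DEG = 90.0  # methyl symmetry axis vs H-H vector


def p2(x: float) -> float:
    """Second Legendre polynomial P2(x) = (3x^2 - 1)/2."""
    return 0.5 * (3.0 * x * x - 1.0)


def omega_larmor(gamma: float, b0: float) -> float:
    """Angular Larmor frequency (rad/s) for gyromagnetic ratio gamma at B0 (T)."""
    return gamma * b0
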
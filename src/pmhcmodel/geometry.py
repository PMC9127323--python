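"""Ideal peptide-backbone geometry shared by the fixture generator and the
restraint builder.

All lengths are in Angstrom, all angles in degrees. The constants are the
standard Engh/Huber-style values used throughout comparative modelling;
restraints and synthetic structures are built from the *same* table so that
an ideal fixture sits at the minimum of the bonded objective.
"""

from __future__ import annotations

import math

import numpy as np

# Bond lengths (Å)
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33  # peptide bond
BOND_C_O = 1.23
BOND_CA_CB = 1.52

# Bond angles (degrees)
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.5
ANGLE_C_N_CA = 121.5
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5
ANGLE_C_CA_CB = 110.1

OMEGA_TRANS = 180.0

# Canonical (phi, psi) per conformation
PHI_PSI = {
    "extended": (-139.0, 135.0),
    "helix": (-57.0, -47.0),
}


def third_side(a: float, b: float, theta_deg: float) -> float:
    """Distance across a bond angle: the 1-3 distance of an a-b triangle
    with apex angle theta (law of cosines)."""
    t = math.radians(theta_deg)
    return math.sqrt(a * a + b * b - 2.0 * a * b * math.cos(t))


# 1-3 distances implied by the angle table; used as distance restraints
# standing in for bond-angle terms.
D13_N_C = third_side(BOND_N_CA, BOND_CA_C, ANGLE_N_CA_C)
D13_CA_N_NEXT = third_side(BOND_CA_C, BOND_C_N, ANGLE_CA_C_N)
D13_C_CA_NEXT = third_side(BOND_C_N, BOND_N_CA, ANGLE_C_N_CA)
D13_CA_O = third_side(BOND_CA_C, BOND_C_O, ANGLE_CA_C_O)
D13_N_CB = third_side(BOND_N_CA, BOND_CA_CB, ANGLE_N_CA_CB)
D13_C_CB = third_side(BOND_CA_C, BOND_CA_CB, ANGLE_C_CA_CB)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c (NeRF).

    d is at distance ``bond`` from c, with angle b-c-d = ``angle_deg`` and
    torsion a-b-c-d = ``torsion_deg``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    basis = np.stack([bc, m, n], axis=1)
    return c + basis @ d_local


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cβ at the ideal tetrahedral position given backbone N, Cα, C."""
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _cb_reference_distances() -> tuple[float, float, float]:
    """Distances CA-CB, N-CB, C-CB implied by :func:`ideal_cb` on an ideal
    N-CA-C triad; restraints use these so an ideally built residue sits at
    the bonded minimum."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    cb = ideal_cb(n, ca, c)
    return (
        float(np.linalg.norm(cb - ca)),
        float(np.linalg.norm(cb - n)),
        float(np.linalg.norm(cb - c)),
    )


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Build an ideal-geometry backbone (N, CA, C, O per residue) from a list
    of per-residue (phi, psi) dihedrals. Omega is fixed trans. The phi of the
    first residue is undefined and ignored.
    """
    nres = len(phi_psi)
    if nres < 1:
        raise ValueError("need at least one residue")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, nres):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        phi_i = phi_psi[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # Carbonyl oxygens: trans to the following amide nitrogen, expressed as a
    # torsion of psi + 180 about the CA-C axis so the last residue needs no
    # successor.
    for i in range(nres):
        psi_i = phi_psi[i][1]
        r = res[i]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
    return res


D_CA_CB, D13_N_CB_EFF, D13_C_CB_EFF = _cb_reference_distances()
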
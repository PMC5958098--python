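"""Idealized polypeptide geometry: internal-coordinate tables and builders.

The coarse residue representation used throughout the package carries the
backbone (N, CA, C, O), the amide and alpha protons (HN, HA), and a single
beta carbon with one pseudo beta proton (CB, HB) standing in for the side
chain.  Glycine lacks CB/HB.  This is the "all-backbone plus selected side
chain" level at which the synthetic trimers and the annealer operate.
"""

from __future__ import annotations

import numpy as np

# Ideal bond lengths (Å) and angles (degrees).
BOND = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N+"): 1.329,   # peptide bond to the next residue
    ("C", "O"): 1.231,
    ("N", "HN"): 0.980,
    ("CA", "HA"): 1.090,
    ("CA", "CB"): 1.530,
    ("CB", "HB"): 1.090,
}

ANGLE = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N+"): 116.2,
    ("C-", "N", "CA"): 121.7,
    ("CA", "C", "O"): 120.8,
    ("C-", "N", "HN"): 119.5,
}

OMEGA = 180.0  # trans peptide

# Torsion-angle atom quadruples resolvable on this representation.  chi1/chi2
# follow the standard definitions; the gamma/delta atoms they reference only
# exist on models that carry full side chains (e.g. deposited coordinates).
TORSION_ATOMS = {
    "phi": (("C", -1), ("N", 0), ("CA", 0), ("C", 0)),
    "psi": (("N", 0), ("CA", 0), ("C", 0), ("N", 1)),
    "chi1": (("N", 0), ("CA", 0), ("CB", 0), ("CG", 0)),
    "chi2": (("CA", 0), ("CB", 0), ("CG", 0), ("CD", 0)),
}

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         r: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A-B-C with bond r = |C-D|,
    angle theta = B-C-D and torsion tau = A-B-C-D (natural extension
    reference frame construction)."""
    theta = np.deg2rad(theta_deg)
    tau = np.deg2rad(tau_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = r * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), -np.sin(theta) * np.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# Tetrahedral branching at CA: CB and HA flank the N/C bisector plane.
_TETRA_OUT = 54.75  # degrees off the reversed bisector


def _branch_dirs(n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    u_n = _unit(n - ca)
    u_c = _unit(c - ca)
    bis = _unit(u_n + u_c)
    m = _unit(np.cross(u_c, u_n))  # sign chosen to give the L configuration
    ct = np.cos(np.deg2rad(_TETRA_OUT))
    st = np.sin(np.deg2rad(_TETRA_OUT))
    cb_dir = -bis * ct + m * st
    ha_dir = -bis * ct - m * st
    return cb_dir, ha_dir


def build_backbone(torsions: list[tuple[float, float]]) -> list[dict]:
    """Build an ideal-geometry backbone from per-residue (phi, psi).

    phi of residue 1 is ignored (no preceding carbonyl); psi of the last
    residue orients its carbonyl oxygen only.  Returns one dict per residue
    with keys N, CA, C.
    """
    n_res = len(torsions)
    if n_res < 1:
        raise ValueError("need at least one residue")
    res = [dict() for _ in range(n_res)]
    res[0]["N"] = np.zeros(3)
    res[0]["CA"] = np.array([BOND[("N", "CA")], 0.0, 0.0])
    # first C in the xy-plane
    theta = np.deg2rad(ANGLE[("N", "CA", "C")])
    res[0]["C"] = res[0]["CA"] + BOND[("CA", "C")] * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(n_res - 1):
        phi_next = torsions[i + 1][0]
        psi = torsions[i][1]
        res[i + 1]["N"] = nerf(
            res[i]["N"], res[i]["CA"], res[i]["C"],
            BOND[("C", "N+")], ANGLE[("CA", "C", "N+")], psi,
        )
        res[i + 1]["CA"] = nerf(
            res[i]["CA"], res[i]["C"], res[i + 1]["N"],
            BOND[("N", "CA")], ANGLE[("C-", "N", "CA")], OMEGA,
        )
        res[i + 1]["C"] = nerf(
            res[i]["C"], res[i + 1]["N"], res[i + 1]["CA"],
            BOND[("CA", "C")], ANGLE[("N", "CA", "C")], phi_next,
        )
    return res


def decorate_backbone(res: list[dict], torsions, res_letters: str) -> list[dict]:
    """Add O, HN, HA, CB, HB to a bare N/CA/C backbone (in place)."""
    n_res = len(res)
    for i in range(n_res):
        psi = torsions[i][1]
        # carbonyl O anti to the next amide nitrogen
        res[i]["O"] = nerf(
            res[i]["N"], res[i]["CA"], res[i]["C"],
            BOND[("C", "O")], ANGLE[("CA", "C", "O")], psi + 180.0,
        )
        if i > 0:
            # amide proton in the peptide plane, anti to the carbonyl oxygen
            res[i]["HN"] = nerf(
                res[i - 1]["O"], res[i - 1]["C"], res[i]["N"],
                BOND[("N", "HN")], ANGLE[("C-", "N", "HN")], 180.0,
            )
        else:
            res[i]["HN"] = nerf(
                res[i]["C"], res[i]["CA"], res[i]["N"],
                BOND[("N", "HN")], 118.0, 180.0,
            )
        cb_dir, ha_dir = _branch_dirs(res[i]["N"], res[i]["CA"], res[i]["C"])
        res[i]["HA"] = res[i]["CA"] + BOND[("CA", "HA")] * ha_dir
        if res_letters[i] != "G":
            cb = res[i]["CA"] + BOND[("CA", "CB")] * cb_dir
            res[i]["CB"] = cb
            # one pseudo beta proton standing in for the side-chain protons
            res[i]["HB"] = cb + BOND[("CB", "HB")] * _unit(cb - res[i]["CA"])
    return res


ATOM_ORDER = ["N", "HN", "CA", "HA", "CB", "HB", "C", "O"]
ELEMENT_OF = {
    "N": "N", "HN": "H", "CA": "C", "HA": "H",
    "CB": "C", "HB": "H", "C": "C", "O": "O",
}


def chain_arrays(res: list[dict], res_letters: str, chain_id: str):
    """Flatten per-residue atom dicts into Conformer-style parallel arrays."""
    chain, idx, rnames, anames, elem, coords = [], [], [], [], [], []
    for i, rd in enumerate(res):
        for name in ATOM_ORDER:
            if name not in rd:
                continue
            chain.append(chain_id)
            idx.append(i + 1)
            rnames.append(THREE_LETTER[res_letters[i]])
            anames.append(name)
            elem.append(ELEMENT_OF[name])
            coords.append(rd[name])
    return chain, idx, rnames, anames, elem, np.array(coords)


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t, rmsd) with proper rotation R (det = +1) such that
    ``mobile @ R.T + t`` best fits ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    P = mobile - cm
    Q = target - ct
    sv = np.linalg.svd(Q, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("superposition target atoms are collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def reference_geometry() -> dict:
    """Equilibrium distances / chirality targets measured on an ideal build.

    All returned pairs are separated by at most two bonds (or locked by the
    trans peptide), so their distances are conformation independent; they
    define the harmonic geometry terms of the annealer's energy model.
    """
    torsions = [(-120.0, 120.0)] * 3
    res = build_backbone(torsions)
    decorate_backbone(res, torsions, "AAA")
    r0, r1 = res[0], res[1]

    def d(a, b):
        return float(np.linalg.norm(a - b))

    pairs13 = {
        # within one residue
        ("N", "C"): d(r1["N"], r1["C"]),
        ("N", "HA"): d(r1["N"], r1["HA"]),
        ("N", "CB"): d(r1["N"], r1["CB"]),
        ("C", "HA"): d(r1["C"], r1["HA"]),
        ("C", "CB"): d(r1["C"], r1["CB"]),
        ("HA", "CB"): d(r1["HA"], r1["CB"]),
        ("HN", "CA"): d(r1["HN"], r1["CA"]),
        ("CA", "O"): d(r1["CA"], r1["O"]),
        ("CA", "HB"): d(r1["CA"], r1["HB"]),
        # across the peptide bond
        ("CA", "N+"): d(r0["CA"], r1["N"]),
        ("O", "N+"): d(r0["O"], r1["N"]),
        ("C", "CA+"): d(r0["C"], r1["CA"]),
        ("C", "HN+"): d(r0["C"], r1["HN"]),
        # omega-locked 1-4 backbone pair (trans peptide)
        ("CA", "CA+"): d(r0["CA"], r1["CA"]),
        ("O", "HN+"): d(r0["O"], r1["HN"]),
    }
    v_ncc_cb = float(
        np.dot(
            np.cross(r1["N"] - r1["CA"], r1["C"] - r1["CA"]),
            r1["CB"] - r1["CA"],
        )
    )
    return {"pairs13": pairs13, "chirality_cb": v_ncc_cb}
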
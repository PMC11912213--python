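"""Ensemble structural descriptors for selected minima.

Kabsch superposition and RMSD/RMSF, radius of gyration, inter-residue
distance and contact maps, Shrake-Rupley solvent-accessible surface area
with a polar/hydrophobic partition, and sequence bookkeeping (hydrophobic
content, formal charge) for amyloid-beta peptides.

The residue classification reproduces the printed hydrophobic counts for
Abeta28/40/42 (11/23/25) only when glycine is counted hydrophobic, so the
hydrophobic class here is {G, A, V, L, I, P, F, M, W}.  Formal charges use
fixed values at neutral pH with histidine neutral and free termini
cancelling (+1/-1), the simplest model giving the peptides' net charge of
-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# -- residue bookkeeping ----------------------------------------------------

#: Hydrophobic one-letter codes (glycine included; see module docstring).
HYDROPHOBIC = frozenset("GAVLIPFMW")

#: Formal side-chain charges at neutral pH (histidine neutral).
FORMAL_CHARGE = {
    "D": -1, "E": -1, "K": +1, "R": +1, "H": 0,
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Canonical amyloid-beta sequences (Abeta28 is the first 28 residues of the
#: extracellular domain; Abeta40/42 extend into the transmembrane stretch).
ABETA28 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNK"
ABETA40 = ABETA28 + "GAIIGLMVGGVV"
ABETA42 = ABETA40 + "IA"

ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "S": 32.06, "P": 30.974, "NA": 22.990}

#: Bondi van der Waals radii (Angstrom) for SASA.
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
               "S": 1.80, "P": 1.80}


def _check_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - STANDARD_AA)
    if bad:
        raise ValueError(f"nonstandard residue letter(s): {bad}")
    return seq


def hydrophobic_content(sequence: str) -> tuple[int, float]:
    """Count and fraction of hydrophobic residues in a one-letter sequence."""
    seq = _check_sequence(sequence)
    count = sum(1 for aa in seq if aa in HYDROPHOBIC)
    return count, count / len(seq)


def net_formal_charge(sequence: str) -> int:
    """Net formal charge at neutral pH, free termini included (they cancel)."""
    seq = _check_sequence(sequence)
    return sum(FORMAL_CHARGE.get(aa, 0) for aa in seq)  # +1 (N-term) -1 (C-term)


# -- structures -------------------------------------------------------------

@dataclass
class Structure:
    """One conformation: parallel per-atom arrays plus residue metadata.

    ``ss_labels`` are optional per-residue secondary-structure letters
    (H/E/C), typically collapsed from externally computed DSSP output.
    """

    atom_names: list[str]
    residue_index: np.ndarray        # (n_atoms,) 1-based residue numbers
    sequence: str                    # one-letter, length = n_residues
    elements: list[str]
    coords: np.ndarray               # (n_atoms, 3) Angstrom
    ss_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        resids = np.unique(self.residue_index)
        if not np.array_equal(resids, np.arange(1, len(resids) + 1)):
            raise ValueError("residue indices must be contiguous from 1")
        if len(self.sequence) != len(resids):
            raise ValueError("sequence length does not match residue count")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atom_mask(self, selection: str = "default") -> np.ndarray:
        """Boolean atom mask for the named selection.

        ``"default"``: main-chain N, CA, C, O plus all side-chain carbons
        (the RMSF alignment selection); ``"ca"``: alpha carbons only;
        ``"heavy"``: all non-hydrogen atoms; ``"all"``: everything.
        """
        names = np.array(self.atom_names)
        elems = np.array(self.elements)
        if selection == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if selection == "heavy":
            return elems != "H"
        if selection == "ca":
            return names == "CA"
        if selection == "default":
            backbone = np.isin(names, ["N", "CA", "C", "O"])
            side_carbon = (elems == "C") & ~np.isin(names, ["C", "CA"])
            return backbone | side_carbon
        raise ValueError(f"unknown selection {selection!r}")

    def representative_coords(self) -> np.ndarray:
        """Per-residue C-beta coordinates, C-alpha for glycine.

        This is the CASP-style residue position used for distance and
        contact maps.
        """
        out = np.empty((self.n_residues, 3))
        names = np.array(self.atom_names)
        for ri in range(1, self.n_residues + 1):
            sel = self.residue_index == ri
            res_names = names[sel]
            want = "CA" if self.sequence[ri - 1] == "G" else "CB"
            hit = np.nonzero(res_names == want)[0]
            if hit.size == 0 and want == "CB":
                hit = np.nonzero(res_names == "CA")[0]
                if hit.size:
                    logger.warning("residue %d: CB missing, using CA", ri)
            if hit.size == 0:
                raise ValueError(
                    f"residue {ri} ({self.sequence[ri-1]}) has neither CB nor CA"
                )
            out[ri - 1] = self.coords[sel][hit[0]]
        return out


@dataclass
class StructureEnsemble:
    """Conformations sharing one sequence and atom layout."""

    members: list[Structure]
    reference: int = 0               # index of the alignment reference

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ensemble")
        ref = self.members[0]
        for s in self.members[1:]:
            if s.sequence != ref.sequence or s.atom_names != ref.atom_names:
                raise ValueError("ensemble members differ in sequence/atoms")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def sequence(self) -> str:
        return self.members[0].sequence


# -- PDB I/O ---------------------------------------------------------------

def read_pdb(path: str | Path) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into an ensemble."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    members: list[Structure] = []
    for model in structure:
        names, resix, elems, xyz, seq = [], [], [], [], []
        ri = 0
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":
                    continue
                one = THREE_TO_ONE.get(residue.get_resname())
                if one is None:
                    continue
                ri += 1
                seq.append(one)
                for atom in residue:
                    names.append(atom.get_name())
                    resix.append(ri)
                    elems.append((atom.element or atom.get_name()[0]).upper())
                    xyz.append(atom.get_coord())
        members.append(Structure(
            atom_names=names, residue_index=np.array(resix),
            sequence="".join(seq), elements=elems, coords=np.array(xyz),
        ))
    return StructureEnsemble(members=members)


def write_pdb(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file."""
    with open(path, "w") as fh:
        for mi, s in enumerate(ensemble.members, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            serial = 0
            for name, ri, el, (x, y, z) in zip(
                s.atom_names, s.residue_index, s.elements, s.coords
            ):
                serial += 1
                res3 = ONE_TO_THREE[s.sequence[ri - 1]]
                aname = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {aname:<4s}{res3:>4s} A{ri:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {el:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# -- superposition ----------------------------------------------------------

def kabsch_rmsd(
    A: Structure, B: Structure, selection: str = "default"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of B onto A.

    Returns (rotation, translation, rmsd): applying ``x @ R.T + t`` to B's
    selected coordinates superposes them on A's.  A proper rotation
    (det = +1) is enforced.
    """
    mask = A.atom_mask(selection)
    P = A.coords[mask]
    Qc = B.coords[B.atom_mask(selection)]
    if P.shape != Qc.shape or P.shape[0] < 3:
        raise ValueError("selections differ or have fewer than 3 atoms")
    return _kabsch(P, Qc)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    span = max(np.linalg.norm(Pc, axis=1).max(), np.linalg.norm(Qc, axis=1).max())
    if span < 1e-12 or np.linalg.matrix_rank(Qc, tol=1e-9 * max(span, 1.0)) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    diff = Qc @ R.T - Pc
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def rmsd_matrix(
    ensemble: StructureEnsemble, selection: str = "default"
) -> np.ndarray:
    """Symmetric pairwise RMSD matrix over the ensemble (Angstrom)."""
    n = ensemble.n_members
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_rmsd(ensemble.members[i], ensemble.members[j],
                                  selection)
            M[i, j] = M[j, i] = r
    return M


def align_to_reference(
    ensemble: StructureEnsemble, selection: str = "default"
) -> StructureEnsemble:
    """Superpose every member's full coordinates onto the reference."""
    ref = ensemble.members[ensemble.reference]
    aligned = []
    for s in ensemble.members:
        R, t, _ = kabsch_rmsd(ref, s, selection)
        aligned.append(Structure(
            atom_names=s.atom_names, residue_index=s.residue_index,
            sequence=s.sequence, elements=s.elements,
            coords=s.coords @ R.T + t, ss_labels=s.ss_labels,
        ))
    return StructureEnsemble(members=aligned, reference=ensemble.reference)


def rmsf(
    ensemble: StructureEnsemble, selection: str = "default"
) -> np.ndarray:
    """Per-residue positional fluctuation across the aligned ensemble.

    Each member is aligned to the reference on the selection; per residue,
    the centroid of its selected atoms is tracked across members and the
    RMS deviation about the ensemble-mean centroid reported.
    """
    if ensemble.n_members == 1:
        logger.warning("single-member ensemble: RMSF is identically zero")
        return np.zeros(ensemble.members[0].n_residues)
    aligned = align_to_reference(ensemble, selection)
    ref = aligned.members[0]
    mask = ref.atom_mask(selection)
    n_res = ref.n_residues
    cent = np.empty((aligned.n_members, n_res, 3))
    for k, s in enumerate(aligned.members):
        for ri in range(1, n_res + 1):
            sel = mask & (s.residue_index == ri)
            if not sel.any():
                sel = s.residue_index == ri
            cent[k, ri - 1] = s.coords[sel].mean(axis=0)
    mean = cent.mean(axis=0)
    return np.sqrt(((cent - mean) ** 2).sum(axis=2).mean(axis=0))


def radius_of_gyration(s: Structure, mass_weighted: bool = True) -> float:
    """Radius of gyration in Angstrom (mass-weighted by default)."""
    if mass_weighted:
        w = np.array([ATOMIC_MASS.get(el, 12.011) for el in s.elements])
    else:
        w = np.ones(s.n_atoms)
    com = (w[:, None] * s.coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((s.coords - com) ** 2).sum(axis=1)).sum() / w.sum()))


# -- maps -------------------------------------------------------------------

def _pairwise(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def distance_maps(ensemble: StructureEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation of inter-residue distances (C-beta,
    C-alpha for glycine) across the ensemble."""
    stack = np.array([_pairwise(s.representative_coords())
                      for s in ensemble.members])
    return stack.mean(axis=0), stack.std(axis=0)


def binary_contact_map(s: Structure, cutoff: float = 8.0) -> np.ndarray:
    """CASP-style binary contact map with self-connections.

    Contact iff the C-beta (C-alpha for glycine) distance is <= cutoff
    (inclusive); the diagonal is 1.
    """
    d = _pairwise(s.representative_coords())
    A = (d <= cutoff).astype(int)
    np.fill_diagonal(A, 1)
    return A


# -- SASA -------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ], axis=1)


@dataclass
class SASAResult:
    per_atom: np.ndarray             # (n_atoms,) Angstrom^2
    per_residue: np.ndarray          # (n_residues,)
    total: float
    polar: float                     # summed over polar-class residues
    hydrophobic: float               # summed over hydrophobic-class residues


def sasa(
    s: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    default_radius: float | None = None,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's sphere is inflated by the probe radius and sampled with a
    deterministic golden-spiral quadrature; the accessible fraction of the
    points times the sphere area gives the atom's SASA.  Residue totals are
    split into polar and hydrophobic by residue class; the two parts sum to
    the total exactly.
    """
    table = dict(BONDI_RADII if radii is None else radii)
    try:
        r = np.array([table[el] if el in table else _radius_or_raise(
            el, default_radius) for el in s.elements])
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}; pass "
                         "default_radius to accept it") from None
    R = r + probe_radius
    pts = _sphere_points(n_sphere_points)
    n = s.n_atoms
    per_atom = np.empty(n)
    coords = s.coords
    # neighbor prefilter: only atoms whose inflated spheres can overlap
    d2 = ((coords[:, None] - coords[None, :]) ** 2).sum(axis=2)
    for i in range(n):
        cand = np.nonzero(d2[i] < (R[i] + R) ** 2)[0]
        cand = cand[cand != i]
        surface = coords[i] + R[i] * pts
        buried = np.zeros(len(pts), dtype=bool)
        for j in cand:
            dj = ((surface - coords[j]) ** 2).sum(axis=1)
            buried |= dj < R[j] ** 2
        per_atom[i] = 4.0 * np.pi * R[i] ** 2 * (~buried).mean()
    per_res = np.zeros(s.n_residues)
    np.add.at(per_res, s.residue_index - 1, per_atom)
    hydro_mask = np.array([aa in HYDROPHOBIC for aa in s.sequence])
    hydro = float(per_res[hydro_mask].sum())
    polar = float(per_res[~hydro_mask].sum())
    return SASAResult(per_atom=per_atom, per_residue=per_res,
                      total=float(per_atom.sum()), polar=polar,
                      hydrophobic=hydro)


def _radius_or_raise(el: str, default: float | None) -> float:
    if default is None:
        raise KeyError(el)
    return default
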
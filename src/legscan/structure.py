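"""Geometric checks on predicted enzyme-peptide complexes.

Three analyses: disulfide detection between cysteine Sγ atoms (the proposed
covalent-inhibition mechanism couples a P1'-Cys of the peptide to the
catalytic Cys of the enzyme; a bonded S-S pair sits near 2.05 Å), an
S1-pocket engagement proxy (distance from the P1 side chain to the catalytic
Sγ, which catches models that misplace another residue into the pocket), and
Cα RMSD after optimal rigid superposition (Kabsch).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "DisulfideReport",
    "DisulfidePair",
    "EngagementReport",
    "SuperpositionResult",
    "load_structure",
    "detect_disulfides",
    "p1_engagement",
    "superpose_rmsd",
    "ca_rmsd",
]

#: Typical S-S bond is ~2.05 Å; 2.5 Å comfortably separates bonded from
#: merely adjacent thiols.
DEFAULT_SS_CUTOFF = 2.5
#: Coarse "productive binding" proxy: P1 side-chain reference atom within
#: this distance of the catalytic Sγ.
DEFAULT_ENGAGEMENT_CUTOFF = 5.0

#: Side-chain reference atom per residue type (functional tip of the chain);
#: Asn's carboxamide carbon CG is the reference for the canonical P1.
SIDECHAIN_REF = {
    "ASN": "CG", "ASP": "CG", "GLN": "CD", "GLU": "CD", "ARG": "CZ",
    "LYS": "NZ", "HIS": "NE2", "SER": "OG", "THR": "OG1", "CYS": "SG",
    "MET": "SD", "TRP": "NE1", "TYR": "OH", "PHE": "CZ", "LEU": "CG",
    "ILE": "CD1", "VAL": "CB", "ALA": "CB", "PRO": "CG", "GLY": "CA",
}


@dataclass
class StructureModel:
    """Thin wrapper around a gemmi structure (first model only)."""

    structure: gemmi.Structure
    path: Path | None = None

    @property
    def model(self) -> gemmi.Model:
        return self.structure[0]

    def chain(self, name: str) -> gemmi.Chain:
        ch = self.model.find_chain(name)
        if ch is None:
            raise KeyError(f"no chain {name!r} in structure")
        return ch

    def residue(self, chain: str, number: int) -> gemmi.Residue:
        for res in self.chain(chain):
            if res.seqid.num == number:
                return res
        raise KeyError(f"no residue {number} in chain {chain}")

    def atom_pos(self, chain: str, number: int, atom: str) -> np.ndarray | None:
        res = self.residue(chain, number)
        a = res.find_atom(atom, "*")
        if a is None:
            return None
        return np.array([a.pos.x, a.pos.y, a.pos.z])

    def ca_coords(self, chain: str) -> dict[int, np.ndarray]:
        out = {}
        for res in self.chain(chain):
            a = res.find_atom("CA", "*")
            if a is not None:
                out[res.seqid.num] = np.array([a.pos.x, a.pos.y, a.pos.z])
        return out


def load_structure(path: str | Path) -> StructureModel:
    """Read a coordinate file (mmCIF primarily, legacy PDB accepted)."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    return StructureModel(structure=st, path=path)


@dataclass
class DisulfidePair:
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    distance: float
    bonded: bool
    involves_catalytic: bool = False


@dataclass
class DisulfideReport:
    pairs: list[DisulfidePair]
    cutoff: float
    catalytic: tuple[str, int] | None = None

    @property
    def bonded_pairs(self) -> list[DisulfidePair]:
        return [p for p in self.pairs if p.bonded]

    @property
    def catalytic_bonded(self) -> bool:
        return any(p.bonded and p.involves_catalytic for p in self.pairs)


def _cys_sg_atoms(model: StructureModel) -> list[tuple[str, int, np.ndarray]]:
    out = []
    for chain in model.model:
        for res in chain:
            if res.name != "CYS":
                continue
            a = res.find_atom("SG", "*")
            if a is not None:
                out.append((chain.name, res.seqid.num, np.array([a.pos.x, a.pos.y, a.pos.z])))
    return out


def detect_disulfides(
    model: StructureModel,
    catalytic: tuple[str, int] | str | None = None,
    cutoff_A: float = DEFAULT_SS_CUTOFF,
) -> DisulfideReport:
    """Report all Cys-Cys Sγ pairs; pairs within ``cutoff_A`` (Å) are bonded.

    ``catalytic`` names the catalytic Cys as ``(chain, residue number)`` or a
    ``"A:189"`` string; pairs involving it are flagged.  ``"auto"`` picks the
    first Cys of the first chain.
    """
    sgs = _cys_sg_atoms(model)
    if not sgs:
        raise ValueError("structure contains no Cys with an Sγ atom")
    cat: tuple[str, int] | None = None
    if catalytic == "auto":
        cat = (sgs[0][0], sgs[0][1])
    elif isinstance(catalytic, str) and catalytic is not None:
        chain, _, num = catalytic.partition(":")
        cat = (chain, int(num))
    elif catalytic is not None:
        cat = (catalytic[0], int(catalytic[1]))
    if cat is not None:
        try:
            res = model.residue(*cat)
        except KeyError:
            raise ValueError(f"catalytic residue {cat} absent from structure") from None
        if res.name != "CYS":
            raise ValueError(f"catalytic residue {cat} is {res.name}, not Cys")
    pairs = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            ca_, ra, pa = sgs[i]
            cb_, rb, pb = sgs[j]
            d = float(np.linalg.norm(pa - pb))
            pairs.append(
                DisulfidePair(
                    chain_a=ca_,
                    residue_a=ra,
                    chain_b=cb_,
                    residue_b=rb,
                    distance=d,
                    bonded=d <= cutoff_A,
                    involves_catalytic=cat in ((ca_, ra), (cb_, rb)),
                )
            )
    return DisulfideReport(pairs=pairs, cutoff=cutoff_A, catalytic=cat)


@dataclass
class EngagementReport:
    distance: float
    engaged: bool
    nearest_residue: tuple[str, int, str] | None  # chain, number, residue name
    incomplete: bool = False


def p1_engagement(
    model: StructureModel,
    catalytic: tuple[str, int],
    p1_residue: tuple[str, int],
    threshold_A: float = DEFAULT_ENGAGEMENT_CUTOFF,
) -> EngagementReport:
    """S1-pocket occupancy proxy for the P1 residue of a modelled substrate.

    Measures the distance from the P1 side-chain reference atom (Cγ for Asn)
    to the catalytic Sγ and reports which peptide-chain residue actually sits
    nearest to the catalytic Sγ — a model that places, say, a P2'-Lys closer
    than the P1-Asn has misplaced the substrate.  Missing atoms are flagged
    incomplete rather than raised.
    """
    cat_sg = model.atom_pos(catalytic[0], int(catalytic[1]), "SG")
    if cat_sg is None:
        return EngagementReport(float("nan"), False, None, incomplete=True)
    p1_chain, p1_num = p1_residue[0], int(p1_residue[1])
    p1 = model.residue(p1_chain, p1_num)
    ref_name = SIDECHAIN_REF.get(p1.name, "CB")
    ref = model.atom_pos(p1_chain, p1_num, ref_name)
    if ref is None:
        return EngagementReport(float("nan"), False, None, incomplete=True)
    dist = float(np.linalg.norm(ref - cat_sg))

    nearest: tuple[str, int, str] | None = None
    best = np.inf
    for res in model.chain(p1_chain):
        rn = SIDECHAIN_REF.get(res.name, "CB")
        a = res.find_atom(rn, "*") or res.find_atom("CA", "*")
        if a is None:
            continue
        d = float(np.linalg.norm(np.array([a.pos.x, a.pos.y, a.pos.z]) - cat_sg))
        if d < best:
            best = d
            nearest = (p1_chain, res.seqid.num, res.name)
    return EngagementReport(
        distance=dist, engaged=dist <= threshold_A, nearest_residue=nearest
    )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid (rotation + translation, no reflection) superposition.

    Returns the transform mapping ``coords_b`` onto ``coords_a`` and the
    resulting RMSD in Å.  Requires n >= 3 matched, non-collinear points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 matched atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-10) < 2 or np.linalg.matrix_rank(b0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    rot, _ = Rotation.align_vectors(a0, b0)
    R = rot.as_matrix()
    t = ca - R @ cb
    # recompute the RMSD from the transform (align_vectors floors its
    # residual at sqrt(machine epsilon))
    rmsd = float(np.sqrt(np.mean(np.sum((a - (b @ R.T + t)) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def ca_rmsd(model_a: StructureModel, model_b: StructureModel, chain: str) -> SuperpositionResult:
    """Cα RMSD between two structures over the shared residue numbers of a chain.

    Atom pairing is by chain name + residue number intersection; no sequence
    alignment is attempted.
    """
    ca_a = model_a.ca_coords(chain)
    ca_b = model_b.ca_coords(chain)
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared Cα positions in chain {chain}")
    a = np.array([ca_a[i] for i in shared])
    b = np.array([ca_b[i] for i in shared])
    return superpose_rmsd(a, b)
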
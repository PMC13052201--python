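"""Combinatorial enzyme-peptide structure-prediction screening.

A screen enumerates peptide variants from a placeholder template (e.g.
``YVANXX`` varying P1'/P2'), emits one prediction job per peptide, parses the
predictor's confidence output (ipTM, peptide pLDDT, PAE) and ranks the
complexes.  The inter-chain predicted TM-score (ipTM) serves as an affinity
proxy: values above 0.8 indicate high-confidence complexes, below 0.6 likely
modelling failure.  A deterministic mock predictor emits output in the same
file dialect so the whole pipeline runs and is testable without GPUs.

The predictor itself always runs out of process: this module only writes job
files and reads output directories.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .library import AA20, PeptideVariant

__all__ = [
    "ScreenDesign",
    "PredictionJob",
    "ComplexScore",
    "ScreenResult",
    "build_jobs",
    "write_job",
    "read_job",
    "parse_prediction_output",
    "rank_screen",
    "classify_confidence",
    "heatmap_matrix",
    "render_heatmap",
    "mock_predict",
]

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class ScreenDesign:
    """Definition of one in-silico specificity screen.

    The enzyme gets a precomputed multiple sequence alignment; peptide MSAs
    and structural templates are disabled, matching how short substrate
    mimetics are modelled.  ``p1_prime_pos`` is the 1-based template index of
    the P1' position (used by the mock predictor to plant covalent-inhibitor
    geometry for P1'-Cys peptides); ``catalytic_residue`` is the catalytic Cys
    number in the enzyme chain (189 for human legumain, 211 for AtLEGbeta).
    """

    enzyme_id: str
    enzyme_sequence: str
    peptide_template: str
    msa_enzyme: str = "precomputed"
    msa_peptide: str = "off"
    templates: str = "off"
    enzyme_chain: str = "A"
    peptide_chain: str = "B"
    p1_prime_pos: int | None = None
    catalytic_residue: int = 189

    def __post_init__(self) -> None:
        if not self.enzyme_sequence:
            raise ValueError("enzyme sequence must be non-empty")
        if self.msa_peptide != "off" or self.templates != "off":
            raise ValueError("peptide MSAs and structural templates must be off")


@dataclass(frozen=True)
class PredictionJob:
    name: str
    enzyme_id: str
    enzyme_sequence: str
    peptide_sequence: str
    enzyme_chain: str = "A"
    peptide_chain: str = "B"
    msa_enzyme: str = "precomputed"
    seed: int = 1


def build_jobs(design: ScreenDesign, library: list[PeptideVariant], seed: int = 1) -> list[PredictionJob]:
    """One prediction job per unique peptide; duplicates collapse with a warning."""
    if not library:
        raise ValueError("peptide library is empty")
    jobs: list[PredictionJob] = []
    seen: set[str] = set()
    dups = 0
    for v in library:
        if v.sequence in seen:
            dups += 1
            continue
        seen.add(v.sequence)
        jobs.append(
            PredictionJob(
                name=f"{design.enzyme_id}_{v.sequence}",
                enzyme_id=design.enzyme_id,
                enzyme_sequence=design.enzyme_sequence,
                peptide_sequence=v.sequence,
                enzyme_chain=design.enzyme_chain,
                peptide_chain=design.peptide_chain,
                msa_enzyme=design.msa_enzyme,
                seed=seed,
            )
        )
    if dups:
        warnings.warn(f"collapsed {dups} duplicate peptide sequences", stacklevel=2)
    return jobs


def _job_dict(job: PredictionJob) -> dict:
    return {
        "name": job.name,
        "modelSeeds": [job.seed],
        "sequences": [
            {
                "protein": {
                    "id": job.enzyme_chain,
                    "sequence": job.enzyme_sequence,
                    "msa": job.msa_enzyme,
                    "templates": [],
                }
            },
            {
                "protein": {
                    "id": job.peptide_chain,
                    "sequence": job.peptide_sequence,
                    "msa": "off",
                    "templates": [],
                }
            },
        ],
    }


def write_job(job: PredictionJob, path: str | Path) -> Path:
    """Serialize a job to the predictor's JSON input dialect (stable bytes)."""
    path = Path(path)
    path.write_text(json.dumps(_job_dict(job), indent=2, sort_keys=True) + "\n")
    return path


def read_job(path: str | Path) -> PredictionJob:
    d = json.loads(Path(path).read_text())
    enz, pep = d["sequences"][0]["protein"], d["sequences"][1]["protein"]
    name = d["name"]
    enzyme_id = name.rsplit("_", 1)[0] if "_" in name else name
    return PredictionJob(
        name=name,
        enzyme_id=enzyme_id,
        enzyme_sequence=enz["sequence"],
        peptide_sequence=pep["sequence"],
        enzyme_chain=enz["id"],
        peptide_chain=pep["id"],
        msa_enzyme=enz["msa"],
        seed=d["modelSeeds"][0],
    )


@dataclass
class ComplexScore:
    """Confidence summary of one predicted enzyme-peptide complex."""

    peptide: str
    iptm: float
    plddt_mean: float
    plddt_per_residue: np.ndarray
    pae_mean_interchain: float
    model_path: Path | None = None

    def __post_init__(self) -> None:
        self.plddt_per_residue = np.asarray(self.plddt_per_residue, dtype=float)
        if not 0.0 <= self.iptm <= 1.0:
            raise ValueError(f"ipTM {self.iptm} outside [0, 1]")
        if np.any((self.plddt_per_residue < 0) | (self.plddt_per_residue > 100)):
            raise ValueError("pLDDT values outside [0, 100]")
        if len(self.plddt_per_residue) != len(self.peptide):
            raise ValueError("per-residue pLDDT length does not match peptide length")


@dataclass
class ScreenResult:
    """All complex scores of one screen plus the template's placeholder axes."""

    scores: list[ComplexScore]
    peptide_template: str
    placeholder_positions: tuple[int, ...]  # 1-based template indices

    def residue_at(self, score: ComplexScore, position: int) -> str:
        return score.peptide[position - 1]


def _require(d: dict, key: str, fname: str):
    if key not in d:
        raise ValueError(f"{fname}: missing key {key!r}")
    return d[key]


def parse_prediction_output(job_dir: str | Path, peptide_chain: str = "B") -> ComplexScore:
    """Parse one predictor output directory into a ComplexScore.

    Expects a ``*_summary_confidences.json`` (inter-chain predicted TM score),
    a ``*_confidences.json`` (per-atom pLDDTs aligned with the model's atom
    order, PAE matrix over residue tokens) and a ``*_model.cif``.
    """
    job_dir = Path(job_dir)
    summary_path = _single(job_dir, "*_summary_confidences.json")
    conf_path = _single(
        job_dir, "*_confidences.json", exclude="*_summary_confidences.json"
    )
    model_path = _single(job_dir, "*_model.cif")

    summary = json.loads(summary_path.read_text())
    iptm = _require(summary, "iptm", summary_path.name)
    if not isinstance(iptm, (int, float)) or not 0.0 <= iptm <= 1.0:
        raise ValueError(f"{summary_path.name}: iptm value {iptm!r} outside [0, 1]")

    conf = json.loads(conf_path.read_text())
    atom_chains = _require(conf, "atom_chain_ids", conf_path.name)
    atom_plddts = np.asarray(_require(conf, "atom_plddts", conf_path.name), dtype=float)
    token_chains = _require(conf, "token_chain_ids", conf_path.name)
    pae = np.asarray(_require(conf, "pae", conf_path.name), dtype=float)
    if len(atom_chains) != len(atom_plddts):
        raise ValueError(f"{conf_path.name}: atom_chain_ids/atom_plddts length mismatch")

    st = gemmi.read_structure(str(model_path))
    st.setup_entities()
    atoms: list[tuple[str, int]] = []  # (chain, residue number) per atom, model order
    peptide_seq = ""
    for chain in st[0]:
        for res in chain:
            if chain.name == peptide_chain:
                peptide_seq += gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
            for _atom in res:
                atoms.append((chain.name, res.seqid.num))
    if len(atoms) != len(atom_plddts):
        raise ValueError(
            f"{conf_path.name}: {len(atom_plddts)} pLDDT values for {len(atoms)} model atoms"
        )
    pep_mask = np.array([c == peptide_chain for c, _ in atoms])
    if not pep_mask.any():
        raise ValueError(f"{model_path.name}: no atoms in peptide chain {peptide_chain!r}")
    resnums = np.array([r for _, r in atoms])
    per_res = []
    for num in sorted(set(resnums[pep_mask])):
        sel = pep_mask & (resnums == num)
        per_res.append(float(np.mean(atom_plddts[sel])))
    token_chains = np.asarray(token_chains)
    if pae.shape != (len(token_chains), len(token_chains)):
        raise ValueError(f"{conf_path.name}: pae shape {pae.shape} does not match tokens")
    inter = np.not_equal.outer(token_chains, token_chains)
    pae_inter = float(np.mean(pae[inter])) if inter.any() else float("nan")

    return ComplexScore(
        peptide=peptide_seq,
        iptm=float(iptm),
        plddt_mean=float(np.mean(per_res)),
        plddt_per_residue=np.array(per_res),
        pae_mean_interchain=pae_inter,
        model_path=model_path,
    )


def _single(job_dir: Path, pattern: str, exclude: str | None = None) -> Path:
    hits = sorted(job_dir.glob(pattern))
    if exclude is not None:
        hits = [h for h in hits if not h.match(exclude)]
    if len(hits) != 1:
        raise FileNotFoundError(f"{job_dir}: expected exactly one {pattern}, found {len(hits)}")
    return hits[0]


def rank_screen(result: ScreenResult) -> pd.DataFrame:
    """Rank complexes by ipTM (desc), then peptide mean pLDDT (desc), then sequence."""
    if not result.scores:
        raise ValueError("no scores to rank")
    rows = [
        {
            "peptide": s.peptide,
            "iptm": s.iptm,
            "plddt_mean": s.plddt_mean,
            "pae_mean_interchain": s.pae_mean_interchain,
            "confidence": classify_confidence(s.iptm),
        }
        for s in result.scores
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["iptm", "plddt_mean", "peptide"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


def classify_confidence(iptm: float) -> str:
    """Band an ipTM score: >0.8 high, <0.6 low, otherwise intermediate."""
    if not 0.0 <= iptm <= 1.0:
        raise ValueError(f"ipTM {iptm} outside [0, 1]")
    if iptm > 0.8:
        return "high"
    if iptm < 0.6:
        return "low"
    return "intermediate"


def heatmap_matrix(
    result: ScreenResult,
    row_position: int,
    col_position: int,
    fixed: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Project a screen onto a 20x20 ipTM matrix over two placeholder positions.

    ``row_position``/``col_position`` are 1-based template indices of the two
    varying placeholders; any further placeholders must be pinned via
    ``fixed`` (position -> residue).  Cells without a matching complex are NaN.
    """
    fixed = dict(fixed or {})
    varying = {row_position, col_position}
    if row_position == col_position:
        raise ValueError("row and column placeholders must differ")
    for pos in varying:
        if pos not in result.placeholder_positions:
            raise ValueError(f"position {pos} is not a placeholder of {result.peptide_template!r}")
    free = [p for p in result.placeholder_positions if p not in varying and p not in fixed]
    if free:
        raise ValueError(
            f"placeholders at positions {free} must be fixed to a residue for a "
            "two-dimensional projection"
        )
    mat = pd.DataFrame(np.nan, index=list(AA20), columns=list(AA20))
    for s in result.scores:
        if any(s.peptide[p - 1] != res for p, res in fixed.items()):
            continue
        r = s.peptide[row_position - 1]
        c = s.peptide[col_position - 1]
        mat.loc[r, c] = s.iptm
    return mat


def render_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Render an ipTM heatmap with the 0.6 / 0.8 confidence bands marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm

    fig, ax = plt.subplots(figsize=(7, 6))
    bounds = [0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0]
    cmap = plt.get_cmap("viridis", len(bounds) - 1)
    norm = BoundaryNorm(bounds, cmap.N)
    im = ax.imshow(matrix.values, cmap=cmap, norm=norm)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    cbar = fig.colorbar(im, ax=ax, label="ipTM")
    for band in (0.6, 0.8):
        cbar.ax.axhline(band, color="red", lw=1.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def _job_rng(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([seed & 0x7FFFFFFF, sub])


def mock_predict(
    job: PredictionJob,
    preference_table: dict[tuple[int, str], float],
    seed: int,
    out_dir: str | Path,
    base_iptm: float = 0.55,
    noise_sd: float = 0.0,
    p1_prime_pos: int | None = None,
    catalytic_residue: int = 189,
) -> dict:
    """Deterministic stand-in for the structure predictor.

    Writes a complete output directory in the pinned dialect and returns the
    planted truth (``iptm``, peptide per-residue ``plddt``, mean inter-chain
    ``pae``).  The planted ipTM is ``clip(base + sum of position/residue
    contributions + noise, 0, 1)``; peptides carrying Cys at the designated
    P1' position additionally get a 2.05 Å S-S contact to the catalytic Cys
    of the enzyme chain, so downstream disulfide detection has real geometry
    to find.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _job_rng(seed, job.name)
    pep = job.peptide_sequence
    contrib = sum(preference_table.get((i + 1, res), 0.0) for i, res in enumerate(pep))
    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    iptm = float(np.clip(base_iptm + contrib + noise, 0.0, 1.0))
    # planted peptide confidence tracks ipTM, clipped to the pLDDT scale
    plddt_res = np.clip(40.0 + 55.0 * iptm + 2.0 * np.arange(len(pep)) / max(len(pep) - 1, 1), 0, 100)
    pae_inter = float(np.round(1.0 + 29.0 * (1.0 - iptm), 4))

    disulfide = p1_prime_pos is not None and 1 <= p1_prime_pos <= len(pep) and pep[p1_prime_pos - 1] == "C"
    st, atom_order = _mock_structure(job, catalytic_residue, p1_prime_pos if disulfide else None)

    atom_plddts: list[float] = []
    atom_chain_ids: list[str] = []
    for chain_name, resnum in atom_order:
        if chain_name == job.peptide_chain:
            atom_plddts.append(float(np.round(plddt_res[resnum - 1], 4)))
        else:
            atom_plddts.append(90.0)
        atom_chain_ids.append(chain_name)
    n_enz_tokens = 3  # the mock enzyme stub has three residues
    token_chains = [job.enzyme_chain] * n_enz_tokens + [job.peptide_chain] * len(pep)
    n_tok = len(token_chains)
    pae = np.full((n_tok, n_tok), 2.0)
    tok = np.asarray(token_chains)
    pae[np.not_equal.outer(tok, tok)] = pae_inter
    np.fill_diagonal(pae, 0.5)

    (out_dir / f"{job.name}_summary_confidences.json").write_text(
        json.dumps({"iptm": iptm, "ptm": iptm, "name": job.name}, indent=1, sort_keys=True)
    )
    (out_dir / f"{job.name}_confidences.json").write_text(
        json.dumps(
            {
                "atom_chain_ids": atom_chain_ids,
                "atom_plddts": atom_plddts,
                "token_chain_ids": token_chains,
                "pae": pae.tolist(),
            },
            sort_keys=True,
        )
    )
    st.setup_entities()
    st.make_mmcif_document().write_file(str(out_dir / f"{job.name}_model.cif"))
    per_res_truth = np.array([np.round(p, 4) for p in plddt_res])
    inter_mask = np.not_equal.outer(tok, tok)
    return {
        "name": job.name,
        "peptide": pep,
        "iptm": iptm,
        "plddt_per_residue": per_res_truth,
        "plddt_mean": float(np.mean(per_res_truth)),
        "pae_mean_interchain": float(np.mean(pae[inter_mask])),
        "disulfide_planted": bool(disulfide),
        "dir": str(out_dir),
    }


def _mock_structure(
    job: PredictionJob, catalytic_residue: int, disulfide_pos: int | None
) -> tuple[gemmi.Structure, list[tuple[str, int]]]:
    """Minimal two-chain model: a 3-residue enzyme stub around the catalytic
    Cys and one CA (plus SG for Cys) per peptide residue."""
    st = gemmi.Structure()
    st.name = job.name
    model = gemmi.Model("1")
    atom_order: list[tuple[str, int]] = []

    def add_atom(res: gemmi.Residue, name: str, element: str, pos: tuple[float, float, float]):
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*pos)
        a.occ = 1.0
        res.add_atom(a)

    enz = gemmi.Chain(job.enzyme_chain)
    for k, (num, rname) in enumerate(
        [(catalytic_residue - 1, "GLY"), (catalytic_residue, "CYS"), (catalytic_residue + 1, "GLY")]
    ):
        res = gemmi.Residue()
        res.name = rname
        res.seqid = gemmi.SeqId(num, " ")
        x = k * 3.8
        add_atom(res, "CA", "C", (x, 0.0, 0.0))
        atom_order.append((job.enzyme_chain, num))
        if rname == "CYS":
            add_atom(res, "SG", "S", (x, 1.8, 0.0))
            atom_order.append((job.enzyme_chain, num))
        enz.add_residue(res)
    model.add_chain(enz)

    cat_sg = (3.8, 1.8, 0.0)
    pep = gemmi.Chain(job.peptide_chain)
    for i, letter in enumerate(job.peptide_sequence):
        num = i + 1
        res = gemmi.Residue()
        res.name = THREE_LETTER[letter]
        res.seqid = gemmi.SeqId(num, " ")
        x, y = i * 3.8, 8.0
        add_atom(res, "CA", "C", (x, y, 0.0))
        atom_order.append((job.peptide_chain, num))
        if letter == "C":
            if disulfide_pos is not None and num == disulfide_pos:
                # Sγ planted 2.05 Å from the catalytic Sγ
                add_atom(res, "SG", "S", (cat_sg[0], cat_sg[1] + 2.05, cat_sg[2]))
            else:
                add_atom(res, "SG", "S", (x, y + 1.8, 0.0))
            atom_order.append((job.peptide_chain, num))
        pep.add_residue(res)
    model.add_chain(pep)
    st.add_model(model)
    return st, atom_order
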
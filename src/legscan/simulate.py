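"""Synthetic-data generators with known ground truth for every pipeline stage.

Raw spectra, kinetic assay data and predictor outputs for this kind of study
are not deposited in public archives, so each analysis stage here is paired
with a generator that emulates its input with planted truth: Gaussian MALDI
peaks at the computed m/z of each species with planted area fractions, noise
and Δ14 demethylated satellites; initial-velocity data from the kinetic
models with multiplicative noise; mock predictor output directories; and toy
coordinate files with requested distances.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .kinetics import KineticDataset, ModelFit, ProgressCurve, fit_model, model_velocity
from .library import (
    AA20,
    DEMETHYL_MONO,
    PeptideVariant,
    ScaffoldSpec,
    SpeciesSet,
    expected_species,
    enumerate_positional_library,
)
from .maldi import Spectrum
from .screen import ScreenDesign, build_jobs, mock_predict
from .library import enumerate_combinatorial_library

__all__ = [
    "ScanTruth",
    "REFERENCE_KINETICS",
    "twofold_series",
    "fit_reference_assay",
    "gen_spectrum",
    "gen_scan_dataset",
    "gen_kinetic_dataset",
    "gen_progress_curve",
    "gen_screen_fixture",
    "gen_toy_structure",
]


def twofold_series(top: float, n_levels: int) -> np.ndarray:
    """Serial two-fold dilution from ``top`` down, ``n_levels`` concentrations."""
    return top * 0.5 ** np.arange(n_levels)


#: Literature kinetic constants of the fluorogenic legumain substrates used as
#: simulation defaults, together with the assay dilution series they were
#: measured on.  Velocities are in RFU/s, concentrations in µM.
REFERENCE_KINETICS = {
    "hLEG:Z-AAN-AMC": {
        "model": "mm",
        "params": {"Vmax": 400.0, "Km": 55.0},
        "S_grid": twofold_series(100.0, 8),  # 100 .. 0.78 µM
    },
    "hLEG:Z-VAN-AMC": {
        "model": "substrate_inhibition",
        "params": {"Vmax": 7800.0, "Km": 20.0, "Ki": 16.0},
        "S_grid": twofold_series(75.0, 9),  # 75 .. 0.29 µM
    },
    "AtLEGbeta:Z-AAN-AMC": {
        "model": "mm",
        "params": {"Vmax": 400.0, "Km": 337.0},
        "S_grid": twofold_series(1000.0, 8),  # 1000 .. 7.8 µM
    },
}


def fit_reference_assay(
    assay: str, seed: int, replicates: int = 3, cv: float = 0.02
) -> tuple[ModelFit, KineticDataset]:
    """Simulate one reference fluorogenic assay and fit its native model.

    Velocities carry constant-CV noise, so the fit uses relative (1/v)
    weighting — the correct likelihood for that error structure and the usual
    choice for fluorogenic plate assays spanning a wide velocity range.
    """
    ref = REFERENCE_KINETICS[assay]
    ds = gen_kinetic_dataset(
        ref["model"], ref["params"], ref["S_grid"], replicates=replicates, cv=cv, seed=seed
    )
    fit = fit_model(ds, ref["model"], weights=1.0 / ds.v)
    return fit, ds


def gen_spectrum(
    species: SpeciesSet,
    fractions: tuple[float, float, float],
    peak_sigma_da: float = 0.3,
    noise_sd: float = 0.005,
    baseline: float = 0.01,
    seed: int = 0,
    satellite_fraction: float = 0.0,
    mz_step: float = 0.02,
    pad_da: float = 20.0,
) -> Spectrum:
    """Simulate a MALDI spectrum of one cyclization reaction.

    ``fractions`` are the planted (precursor, linear, cyclic) area fractions.
    Each species contributes a Gaussian of width ``peak_sigma_da``; a fraction
    ``satellite_fraction`` of each parent's area is moved to a Δ14 satellite
    at parent - 14.0157 Da.  ``baseline`` is a flat offset relative to the
    tallest peak height; ``noise_sd`` is the per-point coefficient of
    variation of the recorded signal (detector noise grows with counts, so
    the noise is signal-proportional).  Intensities are clipped at zero.
    """
    fp, fl, fc = fractions
    if min(fp, fl, fc) < 0 or fp + fl + fc > 1.0 + 1e-9:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    if not 0.0 <= satellite_fraction < 1.0:
        raise ValueError("satellite_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    total = 1000.0
    peaks: list[tuple[float, float]] = []  # (center m/z, area)
    for key, frac in zip(("precursor", "linear", "cyclic"), (fp, fl, fc)):
        mz0 = species[key].mz_mono
        peaks.append((mz0, frac * total * (1.0 - satellite_fraction)))
        if satellite_fraction > 0:
            peaks.append((mz0 + DEMETHYL_MONO, frac * total * satellite_fraction))
    centers = sorted(c for c, a in peaks if a > 0)
    for c1, c2 in zip(centers, centers[1:]):
        if c2 - c1 < 3 * peak_sigma_da:
            warnings.warn(
                f"species peaks at {c1:.2f} and {c2:.2f} closer than 3 sigma: "
                "quantification bias expected",
                stacklevel=2,
            )
    lo = min(c for c, _ in peaks) - pad_da
    hi = max(c for c, _ in peaks) + pad_da
    mz = np.arange(lo, hi + mz_step, mz_step)
    intensity = np.zeros_like(mz)
    norm = peak_sigma_da * np.sqrt(2.0 * np.pi)
    for center, area in peaks:
        if area > 0:
            intensity += area / norm * np.exp(-0.5 * ((mz - center) / peak_sigma_da) ** 2)
    hmax = intensity.max() if intensity.max() > 0 else total / norm
    intensity += baseline * hmax
    if noise_sd > 0:
        intensity *= 1.0 + rng.normal(0.0, noise_sd, size=mz.size)
    intensity = np.clip(intensity, 0.0, None)
    return Spectrum(mz=mz, intensity=intensity, label=species.variant_id)


@dataclass
class ScanTruth:
    """Planted ground truth of a full positional-scan dataset.

    ``fractions`` maps (site label, residue) to the planted (precursor,
    linear, cyclic) area fractions of that variant's reaction.
    """

    fractions: dict[tuple[str, str], tuple[float, float, float]]
    noise_sd: float = 0.005
    baseline: float = 0.01
    peak_sigma_da: float = 0.3
    satellite_fraction: float = 0.0
    seed: int = 0

    @classmethod
    def random(
        cls,
        sites: tuple[str, ...],
        alphabet: tuple[str, ...] = AA20,
        seed: int = 0,
        **kwargs,
    ) -> "ScanTruth":
        """Random but reproducible truth with every cell defined.

        The alanine reference of each site gets a mid-range cyclic fraction;
        other residues get a fold preference between 0.2x and 3x of it, so
        Ala-normalized matrices span realistic dynamic range without any
        fraction collapsing to zero.
        """
        rng = np.random.default_rng(seed)
        fractions: dict[tuple[str, str], tuple[float, float, float]] = {}
        for site in sites:
            ala_cyclic = 0.15
            for res in alphabet:
                fold = 1.0 if res == "A" else float(rng.uniform(0.2, 3.0))
                fc = ala_cyclic * fold
                fl = float(rng.uniform(0.10, 0.30))
                fp = max(1.0 - fc - fl, 0.02)
                s = fp + fl + fc
                fractions[(site, res)] = (fp / s, fl / s, fc / s)
        return cls(fractions=fractions, seed=seed, **kwargs)

    def expected_matrix(self, readout: str) -> dict[tuple[str, str], float]:
        """Ala-normalized matrix implied by the planted fractions."""
        out = {}
        sites = sorted({s for s, _ in self.fractions})
        for site in sites:
            fp, fl, fc = self.fractions[(site, "A")]
            ref = {"cyclic": fc, "linear": fl, "total_lytic": fl + fc}[readout]
            for (s, res), (p, l, c) in self.fractions.items():
                if s != site:
                    continue
                val = {"cyclic": c, "linear": l, "total_lytic": l + c}[readout]
                out[(site, res)] = val / ref if ref > 0 else float("nan")
        return out


def gen_scan_dataset(
    scaffold: ScaffoldSpec,
    truth: ScanTruth,
    sites: tuple[str, ...] | None = None,
    alphabet: tuple[str, ...] = AA20,
    out_dir: str | Path | None = None,
) -> tuple[list[PeptideVariant], dict[str, Spectrum], dict[str, SpeciesSet]]:
    """Generate one spectrum per scan variant from planted truth.

    Returns the library, spectra keyed by variant id, and the species sets
    used to place the peaks.  With ``out_dir`` set, spectra are also written
    as two-column text files.
    """
    if sites is None:
        sites = tuple(sorted({s for s, _ in truth.fractions}))
    library = enumerate_positional_library(scaffold, list(sites), alphabet)
    spectra: dict[str, Spectrum] = {}
    species_sets: dict[str, SpeciesSet] = {}
    for i, variant in enumerate(library):
        cell = (variant.varied_site, variant.varied_residue)
        if cell not in truth.fractions:
            raise ValueError(f"truth has no fractions for cell {cell}")
        sp = expected_species(
            variant, scaffold, include_demethylated=truth.satellite_fraction > 0
        )
        spec = gen_spectrum(
            sp,
            truth.fractions[cell],
            peak_sigma_da=truth.peak_sigma_da,
            noise_sd=truth.noise_sd,
            baseline=truth.baseline,
            satellite_fraction=truth.satellite_fraction,
            seed=(truth.seed * 100003 + i) % 2**31,
        )
        spectra[sp.variant_id] = spec
        species_sets[sp.variant_id] = sp
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for vid, spec in spectra.items():
            safe = vid.replace('"', "pp").replace("'", "p").replace("=", "_")
            np.savetxt(out_dir / f"{safe}.xy", np.column_stack([spec.mz, spec.intensity]), fmt="%.6f")
    return library, spectra, species_sets


def gen_kinetic_dataset(
    model: str,
    params: dict[str, float],
    S_grid,
    replicates: int = 3,
    cv: float = 0.02,
    seed: int = 1,
    meta: dict | None = None,
) -> KineticDataset:
    """Initial-velocity data from a named kinetic model with multiplicative noise.

    Each replicate velocity is ``v_true * (1 + eps)`` with
    ``eps ~ N(0, cv^2)`` — the constant-CV error structure typical of
    triplicate fluorogenic plate assays.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    S_grid = np.asarray(S_grid, dtype=float)
    v_true = model_velocity(model, S_grid, **params)
    S = np.tile(S_grid, replicates)
    rep = np.repeat(np.arange(replicates), S_grid.size)
    eps = rng.normal(0.0, cv, size=S.size) if cv > 0 else np.zeros(S.size)
    v = np.tile(v_true, replicates) * (1.0 + eps)
    return KineticDataset(S=S, v=v, replicate=rep, meta={"model": model, "params": dict(params), **(meta or {})})


def gen_progress_curve(
    slope: float,
    duration_s: float = 1200.0,
    n_points: int = 121,
    noise_sd: float = 0.0,
    y0: float = 0.0,
    seed: int = 1,
    condition: str = "",
) -> ProgressCurve:
    """Linear fluorescence progress trace with optional additive noise."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    y = y0 + slope * t
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return ProgressCurve(t=t, y=y, condition=condition)


def gen_screen_fixture(
    design: ScreenDesign,
    preference_table: dict[tuple[int, str], float],
    seed: int,
    out_dir: str | Path,
    base_iptm: float = 0.55,
    noise_sd: float = 0.0,
    alphabet: tuple[str, ...] = AA20,
) -> list[dict]:
    """Batch mock-predictor run: one output directory per combinatorial peptide.

    Returns the list of planted truth records (one per job, in job order).
    """
    out_dir = Path(out_dir)
    library = enumerate_combinatorial_library(design.peptide_template, alphabet)
    jobs = build_jobs(design, library, seed=seed)
    truths = []
    for job in jobs:
        truths.append(
            mock_predict(
                job,
                preference_table,
                seed=seed,
                out_dir=out_dir / job.name,
                base_iptm=base_iptm,
                noise_sd=noise_sd,
                p1_prime_pos=design.p1_prime_pos,
                catalytic_residue=design.catalytic_residue,
            )
        )
    return truths


def gen_toy_structure(
    path: str | Path,
    ss_distance: float = 2.05,
    p1_distance: float = 3.0,
    catalytic_residue: int = 189,
    peptide: str = "YVANCR",
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> Path:
    """Write a minimal mmCIF with requested Sγ-Sγ and Cγ(Asn)-Sγ distances.

    Chain A is an enzyme stub whose catalytic Cys Sγ sits at the origin;
    chain B is the peptide, with its Cys Sγ placed ``ss_distance`` Å and its
    Asn Cγ ``p1_distance`` Å from the catalytic Sγ.  An optional rigid
    transform is applied to every atom before writing.
    """
    if ss_distance < 0 or p1_distance < 0:
        raise ValueError("distances must be non-negative")
    from .screen import THREE_LETTER

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)

    def add(res: gemmi.Residue, name: str, element: str, xyz):
        p = R @ np.asarray(xyz, dtype=float) + t
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*p)
        a.occ = 1.0
        res.add_atom(a)

    enz = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "CYS"
    res.seqid = gemmi.SeqId(catalytic_residue, " ")
    add(res, "CA", "C", (-1.8, -0.5, 0.0))
    add(res, "CB", "C", (-1.0, 0.5, 0.0))
    add(res, "SG", "S", (0.0, 0.0, 0.0))
    enz.add_residue(res)
    model.add_chain(enz)

    pep = gemmi.Chain("B")
    for i, letter in enumerate(peptide):
        num = i + 1
        r = gemmi.Residue()
        r.name = THREE_LETTER[letter]
        r.seqid = gemmi.SeqId(num, " ")
        # helical-ish trace so the Cα set is well-conditioned for superposition
        x = 4.0 + i * 3.8
        y = 6.0 + 2.3 * float(np.cos(1.7 * i))
        z = 2.3 * float(np.sin(1.7 * i))
        add(r, "CA", "C", (x, y, z))
        if r.name == "ASN":
            add(r, "CB", "C", (x, y - 1.5, 0.0))
            add(r, "CG", "C", (0.0, p1_distance, 0.0))
        elif r.name == "CYS":
            add(r, "CB", "C", (x, y - 1.5, 0.0))
            add(r, "SG", "S", (ss_distance, 0.0, 0.0))
        pep.add_residue(r)
    model.add_chain(pep)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.make_mmcif_document().write_file(str(path))
    return path
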
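"""File I/O helpers: scaffold YAML, enzyme FASTA, variant/species TSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .library import PeptideVariant, ScaffoldSpec, SpeciesSet

__all__ = [
    "load_scaffold",
    "dump_scaffold",
    "read_fasta",
    "variants_to_frame",
    "frame_to_variants",
    "species_to_frame",
]


def load_scaffold(path: str | Path) -> ScaffoldSpec:
    """Read a scaffold definition from YAML.

    Expected keys: ``template`` (one-letter sequence), ``p_site_map``
    (label -> 1-based index), optional ``fixed_sites`` (index -> residue) and
    ``disulfides`` (list of index pairs).
    """
    data = yaml.safe_load(Path(path).read_text())
    return ScaffoldSpec(
        template=data["template"],
        p_site_map={str(k): int(v) for k, v in data["p_site_map"].items()},
        fixed_sites={int(k): str(v) for k, v in (data.get("fixed_sites") or {}).items()},
        disulfides=tuple(tuple(map(int, pair)) for pair in (data.get("disulfides") or [])),
    )


def dump_scaffold(scaffold: ScaffoldSpec, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "template": scaffold.template,
        "p_site_map": dict(scaffold.p_site_map),
        "fixed_sites": dict(scaffold.fixed_sites),
        "disulfides": [list(p) for p in scaffold.disulfides],
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read enzyme sequences; returns id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def variants_to_frame(variants: list[PeptideVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "library_id": v.library_id,
                "sequence": v.sequence,
                "varied_site": v.varied_site or "",
                "varied_residue": v.varied_residue or "",
            }
            for v in variants
        ]
    )


def frame_to_variants(df: pd.DataFrame) -> list[PeptideVariant]:
    return [
        PeptideVariant(
            sequence=row["sequence"],
            varied_site=row["varied_site"] or None,
            varied_residue=row["varied_residue"] or None,
            library_id=row["library_id"],
        )
        for _, row in df.iterrows()
    ]


def species_to_frame(species_sets: list[SpeciesSet]) -> pd.DataFrame:
    rows = []
    for ss in species_sets:
        for sp in ss:
            rows.append(
                {
                    "variant_id": ss.variant_id,
                    "species": sp.name,
                    "sequence": sp.sequence,
                    "mass_mono": sp.mass_mono,
                    "mass_avg": sp.mass_avg,
                    "mz_mono": sp.mz_mono,
                    "mz_avg": sp.mz_avg,
                }
            )
    return pd.DataFrame(rows)
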
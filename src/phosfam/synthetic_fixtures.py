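"""Seeded synthetic data with known ground truth for every pipeline stage.

Each simulated family is built on a gapped master alignment of fixed
length: every instance keeps a column with probability ``1 - indel_rate``
(Bernoulli deletion), draws an S/T/Y acceptor or a non-acceptor residue
per kept column from the acceptor fractions, and phosphorylates each
acceptor independently at the baseline rate — multiplied by the enrichment
factor (probability capped at 1) inside the designated hotspot columns.
Domains are embedded in proteins with random non-acceptor flanks, so site
positions exercise the envelope arithmetic. Regulatory labels are drawn at
different rates inside and outside the true hotspot columns for ROC and
enrichment tests, and a toy structure (Cα trace on a deterministic curve
plus one side-chain pseudo-atom per residue) supports the geometry stage.

Acceptor fractions default to eukaryotic proteome residue frequencies
(S 8.3%, T 5.5%, Y 2.9%); acceptors are placed independently per row, as
in real domain alignments where S/T/Y columns are only partially
conserved. The default phosphorylation rate (0.15 per acceptor) is set so
that a default family's expected site count (~87 over 30 instances of a
120-column domain) clears the pipeline's own >= 50-sites eligibility
filter with a 4-standard-deviation margin: the hotspot test is only ever
applied to families passing that filter, so null families must pass it
too to be representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    ProteinRecord,
    write_alignment,
    write_fasta,
)
from .structure_features import StructureModel, column_map_from_row

NON_ACCEPTOR_ALPHABET = "ACDEFGHIKLMNPQRVW"
SPECIES = "synthetica"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class SimSpec:
    """Generator parameters; all randomness flows from ``rng_seed``."""

    n_families: int = 1
    instances_per_family: int = 30
    domain_length: int = 120
    acceptor_fraction: tuple[tuple[str, float], ...] = (
        ("S", 0.083), ("T", 0.055), ("Y", 0.029),
    )
    baseline_rate: float = 0.15
    hotspot_columns: tuple[int, ...] = ()
    enrichment_factor: float = 1.0
    indel_rate: float = 0.03
    regulatory_fraction_inside: float = 0.5
    regulatory_fraction_outside: float = 0.05
    flank_range: tuple[int, int] = (10, 30)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = dict(self.acceptor_fraction)
        if set(fracs) != {"S", "T", "Y"}:
            raise ValidationError("acceptor_fraction must cover S, T and Y")
        total = sum(fracs.values())
        if any(v < 0 for v in fracs.values()) or total > 1:
            raise ValidationError("acceptor fractions must be >= 0 and sum to <= 1")
        if total == 0 and self.baseline_rate > 0:
            raise ValidationError("no acceptors but a positive phosphorylation rate")
        for p in (
            self.baseline_rate,
            self.indel_rate,
            self.regulatory_fraction_inside,
            self.regulatory_fraction_outside,
        ):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.enrichment_factor < 1:
            raise ValidationError("enrichment_factor must be >= 1")
        if any(not 1 <= c <= self.domain_length for c in self.hotspot_columns):
            raise ValidationError("hotspot columns outside the domain")
        if self.domain_length < 1 or self.instances_per_family < 1 or self.n_families < 1:
            raise ValidationError("sizes must be positive")

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.acceptor_fraction)


@dataclass
class FamilyFixture:
    """Everything one synthetic family feeds into the pipeline."""

    family_id: str
    records: list[ProteinRecord]
    sites: pd.DataFrame
    domains: pd.DataFrame
    alignment: dict[str, str]  # row_id -> gapped row, master coordinates
    labels: pd.DataFrame
    truth: dict


def _family_rng(spec: SimSpec, family_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(family_index, stream))
    )


def generate_family(spec: SimSpec, family_index: int) -> FamilyFixture:
    """One synthetic family with exact hotspot ground truth."""
    rng = _family_rng(spec, family_index)
    L = spec.domain_length
    fracs = spec.fractions
    thr_s = fracs["S"]
    thr_t = thr_s + fracs["T"]
    thr_y = thr_t + fracs["Y"]
    hot = np.zeros(L, dtype=bool)
    for c in spec.hotspot_columns:
        hot[c - 1] = True
    site_prob = np.minimum(
        1.0, spec.baseline_rate * np.where(hot, spec.enrichment_factor, 1.0)
    )

    family_id = f"F{family_index:03d}"
    records: list[ProteinRecord] = []
    site_rows: list[tuple] = []
    domain_rows: list[tuple] = []
    label_rows: list[tuple] = []
    alignment: dict[str, str] = {}

    for i in range(spec.instances_per_family):
        kept = rng.random(L) >= spec.indel_rate
        if not kept.any():
            kept[0] = True
        u = rng.random(L)
        letters = np.array(list(NON_ACCEPTOR_ALPHABET))[
            rng.integers(0, len(NON_ACCEPTOR_ALPHABET), size=L)
        ]
        residues = np.where(
            u < thr_s, "S", np.where(u < thr_t, "T", np.where(u < thr_y, "Y", letters))
        )
        is_acceptor = u < thr_y
        phospho = kept & is_acceptor & (rng.random(L) < site_prob)

        flank_n = int(rng.integers(spec.flank_range[0], spec.flank_range[1] + 1))
        flank_c = int(rng.integers(spec.flank_range[0], spec.flank_range[1] + 1))
        left = "".join(
            rng.choice(list(NON_ACCEPTOR_ALPHABET), size=flank_n)
        )
        right = "".join(
            rng.choice(list(NON_ACCEPTOR_ALPHABET), size=flank_c)
        )
        sub = "".join(residues[kept])
        protein_id = f"{family_id}_P{i:02d}"
        sequence = left + sub + right
        env_start = flank_n + 1
        env_end = flank_n + len(sub)
        records.append(ProteinRecord(protein_id, sequence, SPECIES))
        domain_rows.append((protein_id, family_id, env_start, env_end))
        row_id = f"{protein_id}/{env_start}-{env_end}"
        alignment[row_id] = "".join(
            residues[c] if kept[c] else "-" for c in range(L)
        )

        kept_cols = np.flatnonzero(kept)  # master column (0-based) of local k
        local_of_col = {int(c): k + 1 for k, c in enumerate(kept_cols)}
        for c in np.flatnonzero(phospho):
            local = local_of_col[int(c)]
            position = env_start - 1 + local
            residue = str(residues[c])
            site_rows.append((protein_id, position, residue, SPECIES, "sim"))
            reg_rate = (
                spec.regulatory_fraction_inside
                if hot[c]
                else spec.regulatory_fraction_outside
            )
            label_rows.append(
                (
                    family_id,
                    protein_id,
                    position,
                    "ST" if residue in "ST" else "Y",
                    bool(rng.random() < reg_rate),
                    int(c) + 1,
                )
            )

    sites = pd.DataFrame(
        site_rows, columns=["protein_id", "position", "residue", "species", "source"]
    )
    domains = pd.DataFrame(
        domain_rows, columns=["protein_id", "family_id", "env_start", "env_end"]
    )
    labels = pd.DataFrame(
        label_rows,
        columns=[
            "family_id", "protein_id", "position",
            "residue_class", "is_regulatory", "column",
        ],
    )
    truth = {
        "family_id": family_id,
        "hotspot_columns": [int(c) for c in spec.hotspot_columns],
        "enrichment_factor": spec.enrichment_factor,
        "n_sites": int(len(sites)),
    }
    return FamilyFixture(
        family_id=family_id,
        records=records,
        sites=sites,
        domains=domains,
        alignment=alignment,
        labels=labels,
        truth=truth,
    )


def generate_cohort(spec: SimSpec) -> list[FamilyFixture]:
    return [generate_family(spec, i) for i in range(spec.n_families)]


@dataclass
class StructureFixture:
    """Toy 3D model for one family: PDB text, per-residue features and the
    catalytic residue set, with exactly recomputable geometry."""

    structure_id: str
    row_id: str
    pdb_text: str
    features: pd.DataFrame
    catalytic: tuple[int, ...]
    model: StructureModel


def _ca_trace(n: int, geometry: str) -> np.ndarray:
    if geometry == "line":
        return np.column_stack(
            [3.8 * np.arange(n), np.zeros(n), np.zeros(n)]
        )
    if geometry == "helix":
        # ideal alpha-helix: 2.3 A radius, 1.5 A rise, 100 deg per residue
        theta = np.deg2rad(100.0) * np.arange(n)
        return np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)]
        )
    raise ValueError(f"unknown geometry {geometry!r}")


def generate_structure_fixture(
    spec: SimSpec,
    fixture: FamilyFixture,
    geometry: str = "helix",
    n_catalytic: int = 2,
    disorder_rate: float = 0.2,
    contact_lambda: float = 4.0,
) -> StructureFixture:
    """Build a synthetic structural model from the family's first alignment
    row (Cα on a deterministic curve, one CB pseudo-atom per residue)."""
    family_index = int(fixture.family_id.lstrip("F"))
    rng = _family_rng(spec, family_index, stream=1)
    row_id = next(iter(fixture.alignment))
    gapped = fixture.alignment[row_id]
    sequence = gapped.replace("-", "")
    n = len(sequence)
    ca = _ca_trace(n, geometry)
    cb = ca + np.array([0.9, 0.9, 0.6])  # fixed side-chain offset, ~1.4 A

    structure_id = f"synthetic_{fixture.family_id}_A"
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        res3 = _ONE_TO_THREE[aa]
        for name, xyz, elem in (("CA", ca[i], "C"), ("CB", cb[i], "C")):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    n_cat = min(n_catalytic, n)
    catalytic = tuple(
        sorted(int(c) + 1 for c in rng.choice(n, size=n_cat, replace=False))
    ) if n_cat else ()
    features = pd.DataFrame(
        {
            "structure_id": structure_id,
            "residue_index": np.arange(1, n + 1),
            "rsa_percent": np.round(rng.uniform(0.0, 100.0, size=n), 2),
            "disordered": rng.random(n) < disorder_rate,
            "catalytic": [i + 1 in catalytic for i in range(n)],
            "interface_contact_count": rng.poisson(contact_lambda, size=n),
        }
    )
    model = StructureModel(
        structure_id=structure_id,
        model_sequence=sequence,
        residue_numbers=tuple(range(1, n + 1)),
        ca_coords=ca,
        heavy_atoms=tuple(np.vstack([ca[i], cb[i]]) for i in range(n)),
    )
    column_map_from_row(model, gapped)
    return StructureFixture(
        structure_id=structure_id,
        row_id=row_id,
        pdb_text=pdb_text,
        features=features,
        catalytic=catalytic,
        model=model,
    )


def write_cohort(
    spec: SimSpec,
    fixtures: Sequence[FamilyFixture],
    outdir: str | Path,
    with_structures: bool = True,
) -> None:
    """Emit a cohort as standard-format files plus ``truth.json``.

    Layout: ``proteome.fasta``, ``sites.tsv``, ``domains.tsv``,
    ``labels.tsv``, ``alignments/<family>.afa`` and, when requested,
    ``structures/<id>.pdb`` + ``features.tsv`` + ``catalytic.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    records = [r for f in fixtures for r in f.records]
    write_fasta(records, outdir / "proteome.fasta")
    pd.concat([f.sites for f in fixtures], ignore_index=True).to_csv(
        outdir / "sites.tsv", sep="\t", index=False
    )
    pd.concat([f.domains for f in fixtures], ignore_index=True).to_csv(
        outdir / "domains.tsv", sep="\t", index=False
    )
    pd.concat([f.labels for f in fixtures], ignore_index=True).to_csv(
        outdir / "labels.tsv", sep="\t", index=False
    )
    for f in fixtures:
        write_alignment(f.alignment, outdir / "alignments" / f"{f.family_id}.afa")
    truth = {f.family_id: f.truth for f in fixtures}
    if with_structures:
        (outdir / "structures").mkdir(exist_ok=True)
        feature_frames = []
        catalytic_rows = []
        for f in fixtures:
            sf = generate_structure_fixture(spec, f)
            (outdir / "structures" / f"{sf.structure_id}.pdb").write_text(sf.pdb_text)
            feature_frames.append(sf.features)
            catalytic_rows.extend(
                (sf.structure_id, f.family_id, sf.row_id, c) for c in sf.catalytic
            )
            truth[f.family_id]["structure_id"] = sf.structure_id
            truth[f.family_id]["structure_row"] = sf.row_id
        pd.concat(feature_frames, ignore_index=True).to_csv(
            outdir / "features.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            catalytic_rows,
            columns=["structure_id", "family_id", "row_id", "residue_index"],
        ).to_csv(outdir / "catalytic.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
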
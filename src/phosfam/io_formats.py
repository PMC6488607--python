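"""Readers and writers for every external format the pipeline touches.

All coordinates are 1-based inclusive at these interfaces: protein positions,
domain envelopes, alignment columns and structure residue indices. The gap
character is canonicalized to ``-`` (``.`` accepted on input, Stockholm
dialect). Rows failing cross-validation against the proteome are dropped,
counted and logged — never silently mutated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")
ACCEPTOR_RESIDUES = ("S", "T", "Y")

SITE_COLUMNS = ["protein_id", "position", "residue", "species", "source"]
DOMAIN_COLUMNS = ["protein_id", "family_id", "env_start", "env_end"]
FEATURE_COLUMNS = [
    "structure_id",
    "residue_index",
    "rsa_percent",
    "disordered",
    "catalytic",
    "interface_contact_count",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of a reference proteome."""

    protein_id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("protein record with empty identifier")
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"protein {self.protein_id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def proteome_index(proteome: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index records by id, enforcing uniqueness."""
    index: dict[str, ProteinRecord] = {}
    for rec in proteome:
        if rec.protein_id in index:
            raise FormatError(f"duplicate protein id {rec.protein_id!r}")
        index[rec.protein_id] = rec
    return index


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord` s.

    Sequences are uppercased; duplicate identifiers are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, seq, species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")


def read_site_table(
    path: str | Path, proteome: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Load a phosphosite TSV and cross-validate it against the proteome.

    Schema: ``protein_id  position  residue  species  source`` (1-based
    positions, residue one of S/T/Y). Rows referencing unknown proteins,
    out-of-range positions, non-acceptor residues, or residues disagreeing
    with the protein sequence are dropped with a logged count; duplicate
    (protein_id, position) rows keep the first occurrence. Drop counts are
    stored in ``df.attrs["dropped"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: site table missing columns {sorted(missing)}")
    df = df[SITE_COLUMNS].copy()
    df["position"] = df["position"].astype(int)
    df["residue"] = df["residue"].astype(str).str.upper()
    index = proteome_index(proteome)

    dropped = {
        "unknown_protein": 0,
        "non_acceptor_residue": 0,
        "out_of_range": 0,
        "residue_mismatch": 0,
        "duplicate": 0,
    }
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        rec = index.get(row.protein_id)
        if rec is None:
            dropped["unknown_protein"] += 1
            keep[i] = False
        elif row.residue not in ACCEPTOR_RESIDUES:
            dropped["non_acceptor_residue"] += 1
            keep[i] = False
        elif not 1 <= row.position <= len(rec):
            dropped["out_of_range"] += 1
            keep[i] = False
        elif rec.sequence[row.position - 1] != row.residue:
            dropped["residue_mismatch"] += 1
            keep[i] = False
    df = df[keep]
    n_dup = int(df.duplicated(subset=["protein_id", "position"]).sum())
    if n_dup:
        dropped["duplicate"] = n_dup
        df = df.drop_duplicates(subset=["protein_id", "position"], keep="first")
    total = sum(dropped.values())
    if total:
        logger.warning("%s: dropped %d site rows (%s)", path, total, dropped)
    df = df.reset_index(drop=True)
    df.attrs["dropped"] = dropped
    return df


def read_domain_table(
    path: str | Path, proteome: Sequence[ProteinRecord] | None = None
) -> pd.DataFrame:
    """Load domain instances from a TSV or a pfam_scan-style table.

    A header line containing ``protein_id`` selects the TSV schema
    (``protein_id family_id env_start env_end``); otherwise whitespace-
    separated pfam_scan output is assumed (seq id, aln start/end, envelope
    start/end, hmm acc, hmm name, ...), with the accession (version
    stripped) used as ``family_id``.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty domain table")
    rows: list[tuple[str, str, int, int]] = []
    if "protein_id" in lines[0]:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
        missing = set(DOMAIN_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: domain table missing columns {sorted(missing)}")
        rows = [
            (str(r.protein_id), str(r.family_id), int(r.env_start), int(r.env_end))
            for r in df.itertuples(index=False)
        ]
    else:
        for ln in lines:
            fields = ln.split()
            if len(fields) < 6:
                raise FormatError(f"{path}: unparseable pfam_scan line: {ln!r}")
            acc = fields[5].split(".")[0]
            rows.append((fields[0], acc, int(fields[3]), int(fields[4])))

    out = pd.DataFrame(rows, columns=DOMAIN_COLUMNS)
    bad = out[out.env_start > out.env_end]
    if len(bad):
        raise ValidationError(f"{path}: env_start > env_end in {len(bad)} rows")
    if (out.env_start < 1).any():
        raise ValidationError(f"{path}: envelope start below 1")
    if out.duplicated().any():
        raise ValidationError(f"{path}: identical (protein, family, envelope) rows")
    if proteome is not None:
        index = proteome_index(proteome)
        for r in out.itertuples(index=False):
            rec = index.get(r.protein_id)
            if rec is None:
                raise ValidationError(f"{path}: unknown protein {r.protein_id!r}")
            if r.env_end > len(rec):
                raise ValidationError(
                    f"{path}: envelope {r.protein_id}/{r.env_start}-{r.env_end} "
                    f"exceeds protein length {len(rec)}"
                )
    return out


def read_alignment(path: str | Path, fmt: str = "afa") -> dict[str, str]:
    """Read a gapped alignment (aligned FASTA or Stockholm) as id → row.

    Gap characters are normalized to ``-``; residues uppercased; row order
    preserved. Ragged rows raise :class:`FormatError`.
    """
    bio_fmt = {"afa": "fasta", "fasta": "fasta", "stockholm": "stockholm"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unknown alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), bio_fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows: dict[str, str] = {}
    for rec in aln:
        if rec.id in rows:
            raise FormatError(f"{path}: duplicate alignment row id {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper().replace(".", "-")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: ragged alignment rows (lengths {sorted(lengths)})")
    return rows


def write_alignment(rows: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in rows.items():
            fh.write(f">{rid}\n{row}\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Load a per-residue structural feature TSV (RSA, disorder, catalytic
    flag, interface contact count)."""
    df = pd.read_csv(path, sep="\t", dtype={"structure_id": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: feature table missing columns {sorted(missing)}")
    df = df[FEATURE_COLUMNS].copy()
    df["residue_index"] = df["residue_index"].astype(int)
    df["rsa_percent"] = df["rsa_percent"].astype(float)
    df["disordered"] = df["disordered"].astype(bool)
    df["catalytic"] = df["catalytic"].astype(bool)
    df["interface_contact_count"] = df["interface_contact_count"].astype(int)
    if ((df.rsa_percent < 0) | (df.rsa_percent > 100)).any():
        raise ValidationError(f"{path}: rsa_percent outside [0, 100]")
    if (df.interface_contact_count < 0).any():
        raise ValidationError(f"{path}: negative interface contact count")
    return df


# --- PDB ---------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_pdb_ca(path: str | Path, chain: str):
    """Read one chain of a PDB file into a :class:`StructureModel`.

    Keeps one Cα per residue plus all heavy atoms for minimum-distance
    queries. Altloc conflicts are resolved by highest occupancy, ties by
    alphabetical altloc id; non-standard residues are skipped with a
    warning; a missing chain is an error.
    """
    from .structure_features import StructureModel  # local import: one-way dep

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sparse toy headers
        structure = PDBParser(QUIET=True).get_structure("model", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain not in chains:
        raise ValidationError(
            f"{path}: chain {chain!r} not present (have {sorted(chains)})"
        )

    seq: list[str] = []
    numbers: list[int] = []
    ca: list[np.ndarray] = []
    heavy: list[np.ndarray] = []
    for res in chains[chain]:
        hetflag, resseq, _icode = res.id
        if hetflag.strip():
            continue
        one = _THREE_TO_ONE.get(res.resname.strip().upper())
        if one is None:
            logger.warning("%s: skipping non-standard residue %s", path, res.resname)
            continue
        def _resolve(atom):
            # altloc tie-break: highest occupancy, then alphabetical altloc
            if atom.is_disordered():
                return max(
                    atom.disordered_get_list(),
                    key=lambda a: (a.get_occupancy() or 0.0,
                                   -ord(a.get_altloc() or "~")),
                )
            return atom

        atoms = {}
        for raw in res.get_list():
            atom = _resolve(raw)
            if atom.element == "H":
                continue
            atoms.setdefault(atom.get_name(), atom)
        if "CA" not in atoms:
            logger.warning("%s: residue %s%d lacks a CA atom; skipped",
                           path, res.resname, resseq)
            continue
        seq.append(one)
        numbers.append(int(resseq))
        ca.append(np.asarray(atoms["CA"].coord, dtype=float))
        heavy.append(np.array([a.coord for a in atoms.values()], dtype=float))
    if not seq:
        raise FormatError(f"{path}: chain {chain!r} has no standard residues")
    return StructureModel(
        structure_id=f"{Path(path).stem}_{chain}",
        model_sequence="".join(seq),
        residue_numbers=tuple(numbers),
        ca_coords=np.vstack(ca),
        heavy_atoms=tuple(heavy),
    )


# --- result tables -----------------------------------------------------

REGION_COLUMNS = [
    "family_id", "start_col", "end_col", "n_significant",
    "significant_cols", "min_p", "mean_W",
]
PROFILE_COLUMNS = [
    "family_id", "column", "n_sites", "W", "null_median", "null_sd", "z", "p",
]


def write_region_table(regions: Sequence, path: str | Path) -> None:
    """Serialize hotspot regions to TSV (deterministic column order; shortest
    exact float representation so the table round-trips losslessly)."""
    rows = [
        {
            "family_id": r.family_id,
            "start_col": r.start_col,
            "end_col": r.end_col,
            "n_significant": len(r.significant_cols),
            "significant_cols": ";".join(str(c) for c in r.significant_cols),
            "min_p": r.min_p,
            "mean_W": r.mean_W,
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> list:
    from .hotspot_stats import HotspotRegion

    df = pd.read_csv(path, sep="\t", dtype={"family_id": str})
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: region table missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        cols = tuple(int(c) for c in str(r.significant_cols).split(";") if c != "nan")
        out.append(
            HotspotRegion(
                family_id=r.family_id,
                start_col=int(r.start_col),
                end_col=int(r.end_col),
                significant_cols=cols,
                min_p=float(r.min_p),
                mean_W=float(r.mean_W),
            )
        )
    return out


def write_position_profiles(profiles: Mapping[str, object], path: str | Path) -> None:
    """Serialize per-column profiles (one row per family × column)."""
    frames = []
    for family_id in profiles:
        prof = profiles[family_id]
        frames.append(
            pd.DataFrame(
                {
                    "family_id": family_id,
                    "column": np.arange(1, prof.n_columns + 1),
                    "n_sites": prof.n,
                    "W": prof.W,
                    "null_median": prof.m,
                    "null_sd": prof.s,
                    "z": prof.z,
                    "p": prof.p,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)[PROFILE_COLUMNS]
    else:
        df = pd.DataFrame(columns=PROFILE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_position_profiles(path: str | Path) -> dict[str, object]:
    from .hotspot_stats import PositionProfile

    df = pd.read_csv(path, sep="\t", dtype={"family_id": str})
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: profile table missing columns {sorted(missing)}")
    out: dict[str, PositionProfile] = {}
    for family_id, grp in df.groupby("family_id", sort=False):
        grp = grp.sort_values("column")
        if not np.array_equal(grp["column"].to_numpy(), np.arange(1, len(grp) + 1)):
            raise FormatError(f"{path}: non-contiguous columns for {family_id!r}")
        out[family_id] = PositionProfile(
            family_id=family_id,
            n=grp["n_sites"].to_numpy(dtype=int),
            W=grp["W"].to_numpy(dtype=float),
            m=grp["null_median"].to_numpy(dtype=float),
            s=grp["null_sd"].to_numpy(dtype=float),
            z=grp["z"].to_numpy(dtype=float),
            p=grp["p"].to_numpy(dtype=float),
        )
    return out
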
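"""Representative-structure selection and structural annotation of
hotspot regions.

For each family the available 3D models are filtered (internal chain
breaks longer than one residue, or length below 70% of the longest model,
disqualify), clustered by pairwise Cα RMSD after optimal (Kabsch)
superposition with single linkage, and the medoid of the largest cluster
becomes the family representative. Alignment columns are carried onto the
representative's residues, so hotspot regions can be placed in 3D and each
residue annotated with surface accessibility, disorder, catalytic
proximity (sequence and minimum heavy-atom distance) and interface
membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .errors import ValidationError

#: single-linkage RMSD cutoff (Å) separating conformational clusters
DEFAULT_CLUSTER_CUTOFF = 3.5
#: a position is an interface if contacting another chain in >= this many structures
INTERFACE_MIN_CONTACTS = 10
#: accessible means relative surface accessibility above this percentage
RSA_ACCESSIBLE = 20.0


@dataclass
class StructureModel:
    """One chain of one PDB entry, reduced to per-residue coordinates.

    ``column_of_residue`` maps 1-based residue indices (sequential over the
    resolved residues) to 1-based family-alignment columns, where known.
    """

    structure_id: str
    model_sequence: str
    residue_numbers: tuple[int, ...]
    ca_coords: np.ndarray  # (N, 3)
    heavy_atoms: tuple[np.ndarray, ...] = ()
    column_of_residue: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.model_sequence)
        if self.ca_coords.shape != (n, 3):
            raise ValidationError(
                f"{self.structure_id}: expected {n} CA coordinates, got "
                f"{self.ca_coords.shape}"
            )
        if len(self.residue_numbers) != n:
            raise ValidationError(f"{self.structure_id}: residue numbering length mismatch")
        if not np.isfinite(self.ca_coords).all():
            raise ValidationError(f"{self.structure_id}: non-finite coordinates")
        if not self.heavy_atoms:
            self.heavy_atoms = tuple(self.ca_coords[i : i + 1] for i in range(n))
        cols = [c for c in self.column_of_residue.values()]
        if len(cols) != len(set(cols)):
            raise ValidationError(f"{self.structure_id}: column map not injective")

    def __len__(self) -> int:
        return len(self.model_sequence)

    @property
    def max_internal_gap(self) -> int:
        """Longest run of missing residues implied by the author numbering."""
        if len(self.residue_numbers) < 2:
            return 0
        diffs = np.diff(self.residue_numbers)
        return int(max(0, diffs.max() - 1))

    def residue_of_column(self) -> dict[int, int]:
        return {c: r for r, c in self.column_of_residue.items()}


def column_map_from_row(model: StructureModel, gapped_row: str) -> StructureModel:
    """Attach alignment columns to a model from its gapped alignment row.

    The ungapped row must equal the model sequence.
    """
    cols = [i + 1 for i, ch in enumerate(gapped_row) if ch != "-"]
    ungapped = "".join(ch for ch in gapped_row if ch != "-")
    if ungapped != model.model_sequence:
        raise ValidationError(
            f"{model.structure_id}: gapped row does not ungap to the model sequence"
        )
    model.column_of_residue = {i + 1: c for i, c in enumerate(cols)}
    return model


def filter_structures(models: Sequence[StructureModel]) -> list[StructureModel]:
    """Drop models with an internal chain break longer than one residue or
    shorter than 70% of the longest model. Order-independent."""
    if not models:
        raise ValidationError("no structural models to filter")
    longest = max(len(m) for m in models)
    return [
        m for m in models if m.max_internal_gap <= 1 and len(m) >= 0.7 * longest
    ]


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD between two matched point sets after least-squares rigid
    superposition (proper rotation only; reflections excluded)."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValidationError(f"mismatched coordinate sets {A.shape} vs {B.shape}")
    if len(A) < 3:
        raise ValidationError("need at least 3 matched points for superposition")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A @ R.T - B
    return float(np.sqrt((diff * diff).sum() / len(A)))


def matched_ca(
    a: StructureModel, b: StructureModel
) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates of the alignment columns resolved in both models."""
    inv_a = a.residue_of_column()
    inv_b = b.residue_of_column()
    shared = sorted(set(inv_a) & set(inv_b))
    if len(shared) < 3:
        raise ValidationError(
            f"{a.structure_id} / {b.structure_id}: fewer than 3 shared columns"
        )
    ia = [inv_a[c] - 1 for c in shared]
    ib = [inv_b[c] - 1 for c in shared]
    return a.ca_coords[ia], b.ca_coords[ib]


def select_representative(
    models: Sequence[StructureModel],
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> StructureModel:
    """Representative of the most common conformation.

    Pairwise Kabsch RMSD over shared alignment columns, single-linkage
    clustering at ``cluster_cutoff`` Å, then the medoid (minimum mean RMSD
    to cluster mates) of the largest cluster; ties go to the longer model,
    then the lexicographically smaller id.
    """
    if not models:
        raise ValidationError("no structural models")
    if len(models) == 1:
        return models[0]
    n = len(models)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kabsch_rmsd(*matched_ca(models[i], models[j]))
    assignment = fcluster(
        linkage(squareform(dist, checks=False), method="single"),
        t=cluster_cutoff,
        criterion="distance",
    )
    sizes = np.bincount(assignment)
    best_size = sizes.max()
    candidates: list[tuple[float, int, str, int]] = []
    for cluster_id in np.flatnonzero(sizes == best_size):
        members = np.flatnonzero(assignment == cluster_id)
        for i in members:
            others = members[members != i]
            mean_rmsd = float(dist[i, others].mean()) if len(others) else 0.0
            candidates.append(
                (mean_rmsd, -len(models[i]), models[i].structure_id, int(i))
            )
    candidates.sort()
    return models[candidates[0][3]]


@dataclass(frozen=True)
class ResidueAnnotation:
    """Structural annotation of one residue of the representative model.

    Distances to catalytic residues are None when no catalytic residue is
    known (undefined, not zero). Threshold flags are inclusive (<=).
    """

    residue_index: int
    rsa_percent: float
    disordered: bool
    catalytic: bool
    seq_dist_to_catalytic: int | None
    spatial_dist_to_catalytic: float | None
    interface_contact_count: int
    interface: bool
    accessible: bool
    within_5aa_catalytic: bool
    within_5A_catalytic: bool
    within_15A_catalytic: bool
    is_hotspot: bool


def annotate_residues(
    model: StructureModel,
    features: pd.DataFrame,
    catalytic: Iterable[int],
    hotspot_columns: Iterable[int] = (),
    spatial_mode: str = "heavy",
) -> list[ResidueAnnotation]:
    """Join per-residue features with geometry-derived catalytic proximity.

    ``features`` carries ``residue_index``, ``rsa_percent``, ``disordered``,
    ``catalytic``, ``interface_contact_count``; the ``catalytic`` argument
    (residue indices) defines the proximity targets and overrides the table
    flag where given. ``spatial_mode="heavy"`` uses the minimum heavy-atom
    pair distance, ``"ca"`` the Cα–Cα distance.
    """
    if spatial_mode not in ("heavy", "ca"):
        raise ValueError(f"unknown spatial mode {spatial_mode!r}")
    df = features
    if "residue_index" in df.columns:
        df = df.set_index("residue_index")
    cat = sorted(set(int(c) for c in catalytic))
    for c in cat:
        if not 1 <= c <= len(model):
            raise ValidationError(f"catalytic residue {c} outside the model")
    hotspot_cols = set(int(c) for c in hotspot_columns)

    out: list[ResidueAnnotation] = []
    for idx in range(1, len(model) + 1):
        row = df.loc[idx] if idx in df.index else None
        rsa = float(row["rsa_percent"]) if row is not None else 0.0
        disordered = bool(row["disordered"]) if row is not None else False
        contacts = int(row["interface_contact_count"]) if row is not None else 0
        table_cat = bool(row["catalytic"]) if row is not None else False
        is_cat = idx in cat or table_cat

        if cat:
            seq_dist = min(abs(idx - c) for c in cat)
            if spatial_mode == "ca":
                pts = model.ca_coords[idx - 1 : idx]
                spatial = min(
                    float(np.linalg.norm(pts[0] - model.ca_coords[c - 1]))
                    for c in cat
                )
            else:
                pts = model.heavy_atoms[idx - 1]
                spatial = min(
                    float(cdist(pts, model.heavy_atoms[c - 1]).min()) for c in cat
                )
        else:
            seq_dist = None
            spatial = None

        col = model.column_of_residue.get(idx)
        out.append(
            ResidueAnnotation(
                residue_index=idx,
                rsa_percent=rsa,
                disordered=disordered,
                catalytic=is_cat,
                seq_dist_to_catalytic=seq_dist,
                spatial_dist_to_catalytic=spatial,
                interface_contact_count=contacts,
                interface=contacts >= INTERFACE_MIN_CONTACTS,
                accessible=rsa > RSA_ACCESSIBLE,
                within_5aa_catalytic=seq_dist is not None and seq_dist <= 5,
                within_5A_catalytic=spatial is not None and spatial <= 5.0,
                within_15A_catalytic=spatial is not None and spatial <= 15.0,
                is_hotspot=col is not None and col in hotspot_cols,
            )
        )
    return out


def annotations_frame(annotations: Sequence[ResidueAnnotation]) -> pd.DataFrame:
    """Annotations as a DataFrame suitable for feature enrichment tests."""
    return pd.DataFrame(
        {
            "residue_index": [a.residue_index for a in annotations],
            "rsa_percent": [a.rsa_percent for a in annotations],
            "disordered": [a.disordered for a in annotations],
            "catalytic": [a.catalytic for a in annotations],
            "seq_dist_to_catalytic": [
                math.nan if a.seq_dist_to_catalytic is None else a.seq_dist_to_catalytic
                for a in annotations
            ],
            "spatial_dist_to_catalytic": [
                math.nan
                if a.spatial_dist_to_catalytic is None
                else a.spatial_dist_to_catalytic
                for a in annotations
            ],
            "interface_contact_count": [a.interface_contact_count for a in annotations],
            "is_hotspot": [a.is_hotspot for a in annotations],
        }
    )


@dataclass(frozen=True)
class RegionStructureMapping:
    """A hotspot region carried onto a structural model."""

    family_id: str
    start_col: int
    end_col: int
    structure_id: str
    residues: tuple[int, ...]  # mapped residue indices, sorted
    unmapped_columns: tuple[int, ...]
    covered: bool  # False when no column has structural coverage


def map_hotspot_to_structure(region, model: StructureModel) -> RegionStructureMapping:
    """Translate a region's alignment columns through the model's column
    map; columns with no resolved residue are reported as unmapped."""
    inv = model.residue_of_column()
    residues = []
    unmapped = []
    for col in range(region.start_col, region.end_col + 1):
        if col in inv:
            residues.append(inv[col])
        else:
            unmapped.append(col)
    return RegionStructureMapping(
        family_id=region.family_id,
        start_col=region.start_col,
        end_col=region.end_col,
        structure_id=model.structure_id,
        residues=tuple(sorted(residues)),
        unmapped_columns=tuple(unmapped),
        covered=bool(residues),
    )
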
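"""Phosphosite deduplication, mapping onto domain instances, family
eligibility selection, and projection into alignment-column space.

A *domain instance* is one occurrence of a domain family on a protein,
delimited by an envelope interval. Only instances carrying at least one
phosphosite enter a family's alignment; a family is eligible for hotspot
testing once enough independent instances and mapped sites support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ACCEPTOR_RESIDUES, ProteinRecord, proteome_index

#: eligibility defaults: a family must have this many phospho-bearing
#: instances and this many mapped phosphosites to be tested.
MIN_INSTANCES = 10
MIN_SITES = 50


@dataclass(frozen=True)
class DomainInstance:
    """One domain hit on one protein, with its mapped sites in local
    (1-based, envelope-relative) coordinates."""

    family_id: str
    protein_id: str
    env_start: int
    env_end: int
    sequence: str  # protein subsequence over [env_start, env_end]
    sites_local: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.env_start <= self.env_end:
            raise ValidationError(
                f"bad envelope [{self.env_start}, {self.env_end}] "
                f"on {self.protein_id}"
            )
        if len(self.sequence) != self.env_end - self.env_start + 1:
            raise ValidationError(
                f"{self.row_id}: subsequence length {len(self.sequence)} "
                f"does not match envelope"
            )
        for local, residue in self.sites_local:
            if not 1 <= local <= len(self.sequence):
                raise ValidationError(f"{self.row_id}: local site {local} out of range")
            if self.sequence[local - 1] != residue:
                raise ValidationError(
                    f"{self.row_id}: site residue {residue} does not match "
                    f"sequence at local position {local}"
                )

    @property
    def row_id(self) -> str:
        """Alignment row identifier, ``protein/env_start-env_end``."""
        return f"{self.protein_id}/{self.env_start}-{self.env_end}"


@dataclass
class FamilyAlignment:
    """Gapped alignment of one family's phospho-bearing instances, with
    sites and phospho-acceptor residues resolved to alignment columns
    (1-based).

    ``col_of_local[row_id][k]`` is the column of local position ``k+1``;
    ``sites[row_id]`` lists ``(column, residue)`` pairs; ``acceptors``
    maps each row to its S/T/Y columns by residue type.
    """

    family_id: str
    row_ids: tuple[str, ...]
    gapped: dict[str, str]
    n_columns: int
    col_of_local: dict[str, np.ndarray]
    sites: dict[str, tuple[tuple[int, str], ...]]
    acceptors: dict[str, dict[str, np.ndarray]]

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def site_counts(self) -> np.ndarray:
        """Raw per-column phosphosite counts n(c), summed over rows."""
        n = np.zeros(self.n_columns, dtype=np.int64)
        for pairs in self.sites.values():
            for col, _res in pairs:
                n[col - 1] += 1
        return n

    def site_counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in ACCEPTOR_RESIDUES}
        for pairs in self.sites.values():
            for _col, res in pairs:
                out[res] += 1
        return out


def peptide_window(sequence: str, position: int, flank: int = 5) -> str:
    """The ``2*flank + 1``-mer centred on a 1-based position, termini padded
    with ``-``."""
    lo = position - 1 - flank
    hi = position + flank
    left = "-" * max(0, -lo)
    right = "-" * max(0, hi - len(sequence))
    return left + sequence[max(0, lo) : min(len(sequence), hi)] + right


def dedupe_sites(
    sites: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    exempt_species: Iterable[str] = (),
) -> pd.DataFrame:
    """Collapse redundant phosphosites sharing an identical 11-mer peptide
    context within each species.

    Among sites of one species whose ±5-residue windows are identical
    strings, exactly one representative survives (first by sorted
    protein_id, then position). Species listed in ``exempt_species`` —
    those whose source database already restricts to canonical isoforms —
    bypass the peptide rule. Idempotent.
    """
    index = proteome_index(proteome)
    exempt = set(exempt_species)
    df = sites.sort_values(["protein_id", "position"], kind="mergesort")
    windows = [
        peptide_window(index[r.protein_id].sequence, r.position)
        for r in df.itertuples(index=False)
    ]
    keep = np.ones(len(df), dtype=bool)
    seen_by_species: dict[str, set[str]] = {}
    for i, (species, window) in enumerate(zip(df["species"], windows)):
        if species in exempt:
            continue
        seen = seen_by_species.setdefault(species, set())
        if window in seen:
            keep[i] = False
        else:
            seen.add(window)
    out = df[keep].reset_index(drop=True)
    out.attrs["n_deduplicated"] = int((~keep).sum())
    return out


def map_sites_to_domains(
    sites: pd.DataFrame,
    domains: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
) -> list[DomainInstance]:
    """Assign each site to every containing domain instance and return the
    phospho-bearing instances.

    A site falling inside overlapping instances of *different* families is
    assigned to each; inside overlapping instances of the *same* family it
    is counted once, on the instance with the smallest envelope start.
    Instances without any site are dropped (only phospho-bearing sequences
    are aligned).
    """
    index = proteome_index(proteome)
    site_lists: dict[tuple, list[tuple[int, str]]] = {}
    dom_rows = [
        (str(r.protein_id), str(r.family_id), int(r.env_start), int(r.env_end))
        for r in domains.itertuples(index=False)
    ]
    by_protein: dict[str, list[tuple[str, int, int]]] = {}
    for pid, fam, s, e in dom_rows:
        by_protein.setdefault(pid, []).append((fam, s, e))
    for lst in by_protein.values():
        lst.sort(key=lambda t: (t[0], t[1], t[2]))

    for r in sites.itertuples(index=False):
        claimed: set[str] = set()  # families that already took this site
        for fam, s, e in by_protein.get(r.protein_id, ()):
            if s <= r.position <= e and fam not in claimed:
                claimed.add(fam)
                site_lists.setdefault((r.protein_id, fam, s, e), []).append(
                    (r.position - s + 1, r.residue)
                )

    instances = []
    for (pid, fam, s, e), local_sites in sorted(site_lists.items()):
        rec = index[pid]
        if e > len(rec):
            raise ValidationError(
                f"envelope {pid}/{s}-{e} exceeds protein length {len(rec)}"
            )
        instances.append(
            DomainInstance(
                family_id=fam,
                protein_id=pid,
                env_start=s,
                env_end=e,
                sequence=rec.sequence[s - 1 : e],
                sites_local=tuple(sorted(set(local_sites))),
            )
        )
    return instances


def group_by_family(
    instances: Iterable[DomainInstance],
) -> dict[str, list[DomainInstance]]:
    grouped: dict[str, list[DomainInstance]] = {}
    for inst in instances:
        grouped.setdefault(inst.family_id, []).append(inst)
    return grouped


def select_families(
    instances: Iterable[DomainInstance],
    min_instances: int = MIN_INSTANCES,
    min_sites: int = MIN_SITES,
) -> list[str]:
    """Families with at least ``min_instances`` phospho-bearing instances
    and ``min_sites`` mapped phosphosites in total (counted after dedup)."""
    eligible = []
    for fam, insts in sorted(group_by_family(instances).items()):
        n_sites = sum(len(i.sites_local) for i in insts)
        if len(insts) >= min_instances and n_sites >= min_sites:
            eligible.append(fam)
    return eligible


def project_to_alignment(
    instances: Sequence[DomainInstance],
    rows: Mapping[str, str],
    family_id: str | None = None,
) -> FamilyAlignment:
    """Build a :class:`FamilyAlignment` from instances and their gapped
    alignment rows.

    Every instance must have a row keyed by its ``row_id`` whose ungapped
    sequence equals the instance subsequence; sites are walked through the
    gap structure to their columns.
    """
    if not instances:
        raise ValidationError("no instances to project")
    fams = {i.family_id for i in instances}
    if family_id is None:
        if len(fams) != 1:
            raise ValidationError(f"instances span several families: {sorted(fams)}")
        family_id = next(iter(fams))

    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValidationError(f"ragged alignment rows for family {family_id!r}")
    n_columns = lengths.pop()

    row_ids = []
    gapped: dict[str, str] = {}
    col_of_local: dict[str, np.ndarray] = {}
    sites: dict[str, tuple[tuple[int, str], ...]] = {}
    acceptors: dict[str, dict[str, np.ndarray]] = {}
    for inst in instances:
        rid = inst.row_id
        row = rows.get(rid)
        if row is None:
            raise ValidationError(
                f"family {family_id!r}: no alignment row for instance {rid!r}"
            )
        ungapped_cols = np.flatnonzero(np.frombuffer(row.encode(), np.uint8) != ord("-"))
        ungapped = "".join(row[c] for c in ungapped_cols)
        if ungapped != inst.sequence:
            raise ValidationError(
                f"family {family_id!r}: ungapped row {rid!r} does not match "
                f"the instance subsequence"
            )
        cols = ungapped_cols + 1  # 1-based columns
        row_ids.append(rid)
        gapped[rid] = row
        col_of_local[rid] = cols
        sites[rid] = tuple((int(cols[loc - 1]), res) for loc, res in inst.sites_local)
        acceptors[rid] = {
            t: cols[np.frombuffer(inst.sequence.encode(), np.uint8) == ord(t)]
            for t in ACCEPTOR_RESIDUES
        }
    return FamilyAlignment(
        family_id=family_id,
        row_ids=tuple(row_ids),
        gapped=gapped,
        n_columns=n_columns,
        col_of_local=col_of_local,
        sites=sites,
        acceptors=acceptors,
    )


def column_acceptor_counts(aln: FamilyAlignment) -> dict[str, np.ndarray]:
    """Per-column counts of S, T and Y acceptor residues across rows (gaps
    contribute nothing)."""
    out = {t: np.zeros(aln.n_columns, dtype=np.int64) for t in ACCEPTOR_RESIDUES}
    for rid in aln.row_ids:
        for t in ACCEPTOR_RESIDUES:
            np.add.at(out[t], aln.acceptors[rid][t] - 1, 1)
    return out


def local_of_column(aln: FamilyAlignment, row_id: str, column: int) -> int | None:
    """Invert the column map: the local position at ``column`` of a row, or
    None on a gap."""
    cols = aln.col_of_local[row_id]
    idx = np.searchsorted(cols, column)
    if idx < len(cols) and cols[idx] == column:
        return int(idx) + 1
    return None
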
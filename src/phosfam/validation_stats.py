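"""Validation of hotspot calls against known-regulatory sites and
structural features.

Two complementary checks: (i) the hotspot p-value of a site's alignment
column, ranked via -log10(p), should discriminate sites with annotated
regulatory function from the rest (ROC/AUC, Mann-Whitney form with tie
averaging); (ii) hotspot residues should be enriched, relative to other
residues of the same domains, for structural features such as surface
accessibility, disorder, catalytic identity or proximity, and interface
membership (one-sided Fisher's exact tests — enrichment only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata

from .errors import ValidationError

#: A regulatory-enrichment universe keeps only families contributing more
#: than this many regulatory sites of the tested class.
MIN_REGULATORY_PER_FAMILY = 2


@dataclass(frozen=True)
class LabeledSite:
    """One phosphosite with its functional label and hotspot statistics."""

    protein_id: str
    position: int
    residue_class: str  # "ST" or "Y"
    is_regulatory: bool
    hotspot_p: float
    in_hotspot: bool
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.residue_class not in ("ST", "Y"):
            raise ValidationError(f"bad residue class {self.residue_class!r}")
        if not 0 < self.hotspot_p <= 1:
            raise ValidationError(f"hotspot_p {self.hotspot_p} outside (0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 one-sided Fisher test outcome. Table layout::

        [[a, b],     rows: target class (e.g. hotspot / regulatory)
         [c, d]]     cols: feature present / absent

    odds_ratio = (a*d)/(b*c), +inf when b*c == 0.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    test_side: str = "greater"


def roc_auc_from_scores(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the Mann-Whitney rank-sum statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(labeled: Iterable[LabeledSite], residue_class: str) -> float:
    """Discrimination of regulatory from non-regulatory sites of one residue
    class by the hotspot p-value (scored as -log10 p; smaller p ranks
    higher)."""
    sites = [s for s in labeled if s.residue_class == residue_class]
    if not sites:
        raise ValidationError(f"no sites of class {residue_class!r}")
    scores = [-math.log10(s.hotspot_p) for s in sites]
    labels = [s.is_regulatory for s in sites]
    return roc_auc_from_scores(scores, labels)


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """One-sided (greater) Fisher's exact test on [[a, b], [c, d]] with the
    sample odds ratio."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError("Fisher table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency table")
    if b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)
    _or, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=float(p))


_FEATURE_PREDICATES = {
    "accessible": lambda df: df["rsa_percent"] > 20,
    "disordered": lambda df: df["disordered"].astype(bool),
    "catalytic": lambda df: df["catalytic"].astype(bool),
    "within_5aa_catalytic": lambda df: df["seq_dist_to_catalytic"] <= 5,
    "within_5A_catalytic": lambda df: df["spatial_dist_to_catalytic"] <= 5.0,
    "within_15A_catalytic": lambda df: df["spatial_dist_to_catalytic"] <= 15.0,
    "interface": lambda df: df["interface_contact_count"] >= 10,
}


def feature_enrichment(
    hotspot_positions: Iterable[int],
    other_positions: Iterable[int],
    features: pd.DataFrame,
    feature: str,
) -> EnrichmentResult:
    """Enrichment of a structural feature among hotspot residues versus
    other residues of the same domains.

    ``features`` is indexed by (or carries a column) ``residue_index`` with
    the per-residue annotation columns. For ``feature="interface"`` the
    universe is first restricted to accessible residues (RSA > 20%), so the
    test is not confounded by surface exposure. Undefined distances
    (no catalytic residue) count as feature-absent.
    """
    if feature not in _FEATURE_PREDICATES:
        raise ValueError(f"unknown feature {feature!r}")
    df = features
    if "residue_index" in df.columns:
        df = df.set_index("residue_index")
    hot = sorted(set(hotspot_positions))
    other = sorted(set(other_positions) - set(hot))
    universe = df.loc[[i for i in hot + other if i in df.index]]
    if feature == "interface":
        universe = universe[universe["rsa_percent"] > 20]
    if universe.empty:
        raise ValidationError(f"empty universe for feature {feature!r}")
    flag = _FEATURE_PREDICATES[feature](universe).fillna(False)
    is_hot = universe.index.isin(hot)
    a = int((flag & is_hot).sum())
    b = int((~flag & is_hot).sum())
    c = int((flag & ~is_hot).sum())
    d = int((~flag & ~is_hot).sum())
    return fisher_enrichment(a, b, c, d)


def regulatory_enrichment(
    labeled: Iterable[LabeledSite],
    residue_class: str,
    min_regulatory_per_family: int = MIN_REGULATORY_PER_FAMILY,
) -> EnrichmentResult:
    """Enrichment of known-regulatory sites inside hotspot regions versus
    the rest of the domain (per-site universe).

    When sites carry family ids, only families with at least
    ``min_regulatory_per_family`` regulatory sites of the tested class
    enter the universe.
    """
    sites = [s for s in labeled if s.residue_class == residue_class]
    if any(s.family_id for s in sites):
        per_family: dict[str, int] = {}
        for s in sites:
            if s.is_regulatory:
                per_family[s.family_id] = per_family.get(s.family_id, 0) + 1
        keep = {f for f, n in per_family.items() if n >= min_regulatory_per_family}
        sites = [s for s in sites if s.family_id in keep]
    if not sites:
        raise ValidationError("no labeled sites in the regulatory universe")
    a = sum(s.is_regulatory and s.in_hotspot for s in sites)
    b = sum(s.is_regulatory and not s.in_hotspot for s in sites)
    c = sum(not s.is_regulatory and s.in_hotspot for s in sites)
    d = sum(not s.is_regulatory and not s.in_hotspot for s in sites)
    return fisher_enrichment(a, b, c, d)


def labeled_sites_from_tables(
    labels: pd.DataFrame,
    profiles,
    regions: Sequence,
) -> list[LabeledSite]:
    """Join a label table (family_id, protein_id, position, residue_class,
    is_regulatory, column) with per-column profiles and called regions."""
    region_cols: dict[str, set[int]] = {}
    for r in regions:
        region_cols.setdefault(r.family_id, set()).update(
            range(r.start_col, r.end_col + 1)
        )
    out: list[LabeledSite] = []
    for row in labels.itertuples(index=False):
        prof = profiles.get(row.family_id)
        if prof is None:
            continue
        col = int(row.column)
        if not 1 <= col <= prof.n_columns:
            raise ValidationError(
                f"label column {col} outside family {row.family_id!r}"
            )
        out.append(
            LabeledSite(
                protein_id=str(row.protein_id),
                position=int(row.position),
                residue_class=str(row.residue_class),
                is_regulatory=bool(row.is_regulatory),
                hotspot_p=float(prof.p[col - 1]),
                in_hotspot=col in region_cols.get(row.family_id, ()),
                family_id=str(row.family_id),
            )
        )
    return out
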
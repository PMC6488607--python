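"""Rolling-window phospho-density statistics with a permutation null.

The statistic for each alignment column is the mean phosphosite count over
a fixed window centred on it (width 5 by default; edge windows truncated
and averaged over their actual width). The null is generated by randomly
reassigning each sequence's phosphosites to equivalent phospho-acceptor
residues (S→S, T→T, Y→Y), preserving per-type totals — per sequence by
default, or alignment-wide. Over B permutations the per-column median and
standard deviation of the windowed profile define a z-score for the
observed profile, converted to a one-sided p-value with the normal survival
function; only enrichment is scored, never depletion. Significant columns
(globally Bonferroni-corrected p below alpha AND window mean at or above an
effect-size floor) are merged into maximal runs, extended by ±e columns and
fused where the extended intervals meet, yielding hotspot regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .io_formats import ACCEPTOR_RESIDUES
from .site_mapping import FamilyAlignment


@dataclass(frozen=True)
class HotspotParams:
    """Tunable parameters of the hotspot scan.

    window
        Rolling-window width in columns (odd). The window absorbs
        phosphopeptide localization error and alignment uncertainty.
    permutations
        Number of null reassignments B.
    alpha
        Family-wise error rate for the global Bonferroni correction.
    effect_min
        Minimum observed window mean (phosphosites per position) for a
        column to be called, screening out significant-but-tiny effects.
    extension
        Columns added on each side of a merged significant run.
    permutation_scope
        ``per_sequence``: each row's sites are reshuffled among that row's
        own acceptors (preserves row composition). ``per_alignment``:
        type-wise totals are reshuffled across all rows' acceptors.
    type_handling
        ``per_type`` keeps S, T and Y totals separately; ``pooled_ST``
        pools S and T acceptors into one exchangeable class.
    """

    window: int = 5
    permutations: int = 100
    alpha: float = 0.01
    effect_min: float = 2.0
    extension: int = 2
    rng_seed: int = 0
    permutation_scope: str = "per_sequence"
    type_handling: str = "per_type"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.effect_min < 0:
            raise ValueError("effect_min must be >= 0")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if self.permutation_scope not in ("per_sequence", "per_alignment"):
            raise ValueError(f"unknown permutation scope {self.permutation_scope!r}")
        if self.type_handling not in ("per_type", "pooled_ST"):
            raise ValueError(f"unknown type handling {self.type_handling!r}")


@dataclass
class PositionProfile:
    """Per-column observed and null statistics for one family."""

    family_id: str
    n: np.ndarray  # raw site count per column
    W: np.ndarray  # observed window mean
    m: np.ndarray  # null median of the window mean
    s: np.ndarray  # null sd (population, divisor B)
    z: np.ndarray
    p: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.W)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PositionProfile):
            return NotImplemented
        return self.family_id == other.family_id and all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("n", "W", "m", "s", "z", "p")
        )


@dataclass(frozen=True)
class HotspotRegion:
    """A merged, ±e-extended run of significant columns."""

    family_id: str
    start_col: int
    end_col: int
    significant_cols: tuple[int, ...]
    min_p: float
    mean_W: float

    def __post_init__(self) -> None:
        if self.start_col > self.end_col:
            raise ValidationError("region start after end")
        if any(not self.start_col <= c <= self.end_col for c in self.significant_cols):
            raise ValidationError("significant column outside its region")


# --- windowed profile --------------------------------------------------

def sliding_window_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Mean of ``x`` over a centred window of width ``w`` along the last
    axis, truncated (not zero-padded) at the edges."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    half = w // 2
    cs = np.cumsum(x, axis=-1)
    idx = np.arange(n)
    hi = np.minimum(idx + half, n - 1)
    lo = idx - half
    upper = cs[..., hi]
    lower = np.where(lo >= 1, cs[..., np.maximum(lo - 1, 0)], 0.0)
    width = hi - np.maximum(lo, 0) + 1
    return (upper - lower) / width


def window_profile(aln: FamilyAlignment, w: int) -> np.ndarray:
    """Observed per-column window mean W(c) of phosphosite counts."""
    if aln.n_columns == 0 or not aln.row_ids:
        raise ValidationError(f"family {aln.family_id!r}: empty alignment")
    return sliding_window_mean(aln.site_counts(), w)


# --- permutation null --------------------------------------------------

def _site_and_acceptor_groups(
    aln: FamilyAlignment, params: HotspotParams
) -> list[tuple[str, np.ndarray, int]]:
    """(label, acceptor columns 0-based possibly with multiplicity, k sites)
    for every exchangeable group, in fixed order."""
    if params.type_handling == "pooled_ST":
        classes: tuple[tuple[str, ...], ...] = (("S", "T"), ("Y",))
    else:
        classes = (("S",), ("T",), ("Y",))

    groups: list[tuple[str, np.ndarray, int]] = []
    if params.permutation_scope == "per_sequence":
        for rid in aln.row_ids:
            for cls in classes:
                acc = np.concatenate([aln.acceptors[rid][t] for t in cls]) - 1
                k = sum(1 for _c, r in aln.sites[rid] if r in cls)
                if k > len(acc):
                    raise ValidationError(
                        f"row {rid!r}: {k} sites of class {'/'.join(cls)} but "
                        f"only {len(acc)} acceptors"
                    )
                if k:
                    groups.append((f"{rid}:{''.join(cls)}", np.sort(acc), k))
    else:
        for cls in classes:
            acc = np.concatenate(
                [aln.acceptors[rid][t] for rid in aln.row_ids for t in cls]
            ) - 1
            k = sum(
                1 for rid in aln.row_ids for _c, r in aln.sites[rid] if r in cls
            )
            if k > len(acc):
                raise ValidationError(
                    f"family {aln.family_id!r}: {k} sites of class "
                    f"{'/'.join(cls)} but only {len(acc)} acceptor residues"
                )
            if k:
                groups.append((f"*:{''.join(cls)}", np.sort(acc), k))
    return groups


def permute_sites(
    aln: FamilyAlignment, params: HotspotParams, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    """One random reassignment of all sites to acceptor residues.

    Returns the permuted site multiset as ``(group_label, column, residue)``
    triples (columns 1-based); per-type totals — and per-row totals under
    ``per_sequence`` scope — are conserved by construction.
    """
    out: list[tuple[str, int, str]] = []
    for label, acc, k in _site_and_acceptor_groups(aln, params):
        chosen = rng.choice(acc, size=k, replace=False)
        res = label.rsplit(":", 1)[1]
        out.extend((label, int(c) + 1, res) for c in np.sort(chosen))
    return out


def null_window_profiles(
    aln: FamilyAlignment, params: HotspotParams, rng: np.random.Generator
) -> np.ndarray:
    """Window-mean profiles of B independent permutations, shape
    (B, n_columns). Vectorized across permutations."""
    B = params.permutations
    counts = np.zeros((B, aln.n_columns), dtype=np.float64)
    rows_idx = np.arange(B)
    for _label, acc, k in _site_and_acceptor_groups(aln, params):
        a = len(acc)
        if k == a:
            # forced placement: every acceptor is a site
            counts += np.bincount(acc, minlength=aln.n_columns)[None, :]
            continue
        u = rng.random((B, a))
        pick = np.argpartition(u, k - 1, axis=1)[:, :k]
        cols = acc[pick]
        np.add.at(counts, (np.repeat(rows_idx, k), cols.ravel()), 1.0)
    return sliding_window_mean(counts, params.window)


def null_stats(
    aln: FamilyAlignment,
    params: HotspotParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column null median m(c) and standard deviation s(c) of the
    window profile over B permutations (population sd, divisor B).
    Bit-reproducible for a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    profiles = null_window_profiles(aln, params, rng)
    return np.median(profiles, axis=0), profiles.std(axis=0, ddof=0)


def position_pvalues(
    W: np.ndarray, m: np.ndarray, s: np.ndarray, permutations: int
) -> tuple[np.ndarray, np.ndarray]:
    """z-scores and one-sided (enrichment-only) normal-tail p-values.

    Degenerate columns (null sd 0): p = 1 if the observed value does not
    exceed the null, else 1/(B+1), the standard permutation lower bound.
    """
    W = np.asarray(W, float)
    m = np.asarray(m, float)
    s = np.asarray(s, float)
    z = np.zeros_like(W)
    p = np.ones_like(W)
    live = s > 0
    z[live] = (W[live] - m[live]) / s[live]
    p[live] = norm.sf(z[live])
    frozen_excess = ~live & (W > m)
    z[frozen_excess] = np.inf
    p[frozen_excess] = 1.0 / (permutations + 1)
    return z, p


def family_profile(
    aln: FamilyAlignment,
    params: HotspotParams,
    rng: np.random.Generator | None = None,
) -> PositionProfile:
    """Observed + null statistics for one family."""
    n = aln.site_counts()
    W = window_profile(aln, params.window)
    m, s = null_stats(aln, params, rng)
    z, p = position_pvalues(W, m, s, params.permutations)
    return PositionProfile(family_id=aln.family_id, n=n, W=W, m=m, s=s, z=z, p=p)


# --- multiple testing and region calling -------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Uncorrected per-test threshold for a global family-wise alpha."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def significant_columns(
    profile: PositionProfile, threshold: float, effect_min: float
) -> list[int]:
    """Columns (1-based) with p below the global threshold AND window mean
    at or above the effect-size floor."""
    mask = (profile.p < threshold) & (profile.W >= effect_min)
    return [int(c) + 1 for c in np.flatnonzero(mask)]


def merge_significant_columns(
    cols: Sequence[int], n_columns: int, extension: int
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Merge significant columns into ±e-extended regions.

    Maximal runs of contiguous columns are extended by ``extension`` on
    each side, clipped to [1, n_columns]; extended intervals that overlap
    or touch (including adjacency) are fused. Returns
    ``(start, end, member significant columns)`` triples.
    """
    if not cols:
        return []
    cols = sorted(set(cols))
    runs: list[list[int]] = [[cols[0], cols[0]]]
    for c in cols[1:]:
        if c == runs[-1][1] + 1:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    intervals = [
        (max(1, a - extension), min(n_columns, b + extension)) for a, b in runs
    ]
    merged: list[list[int]] = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [
        (a, b, tuple(c for c in cols if a <= c <= b)) for a, b in merged
    ]


def call_hotspots(
    profiles: Mapping[str, PositionProfile],
    params: HotspotParams,
    threshold: float | None = None,
) -> tuple[list[HotspotRegion], float, int]:
    """Call hotspot regions across all families under one global Bonferroni
    correction.

    The test count is every column of every family (the correction is
    global). Returns (regions, uncorrected threshold, n_tests).
    """
    n_tests = sum(prof.n_columns for prof in profiles.values())
    if threshold is None:
        threshold = bonferroni_threshold(params.alpha, n_tests)
    regions: list[HotspotRegion] = []
    for family_id in profiles:
        prof = profiles[family_id]
        sig = significant_columns(prof, threshold, params.effect_min)
        for start, end, members in merge_significant_columns(
            sig, prof.n_columns, params.extension
        ):
            members_idx = np.asarray(members, dtype=int) - 1
            regions.append(
                HotspotRegion(
                    family_id=family_id,
                    start_col=start,
                    end_col=end,
                    significant_cols=members,
                    min_p=float(prof.p[members_idx].min()),
                    mean_W=float(prof.W[members_idx].mean()),
                )
            )
    return regions, threshold, n_tests
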
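"""End-to-end orchestration: sites + domains + alignments in, per-column
profiles and hotspot regions out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hotspot_stats import (
    HotspotParams,
    HotspotRegion,
    PositionProfile,
    call_hotspots,
    family_profile,
)
from .io_formats import ProteinRecord
from .site_mapping import (
    FamilyAlignment,
    dedupe_sites,
    group_by_family,
    map_sites_to_domains,
    project_to_alignment,
    select_families,
)


@dataclass
class DetectionResult:
    params: HotspotParams
    eligible_families: list[str]
    alignments: dict[str, FamilyAlignment]
    profiles: dict[str, PositionProfile]
    regions: list[HotspotRegion]
    threshold: float
    n_tests: int


def detect_hotspots(
    sites: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    domains: pd.DataFrame,
    alignment_rows: Mapping[str, Mapping[str, str]],
    params: HotspotParams,
    exempt_species: Iterable[str] = (),
    min_instances: int | None = None,
    min_sites: int | None = None,
) -> DetectionResult:
    """Run the full hotspot scan.

    ``alignment_rows`` maps family_id to that family's gapped rows (keyed
    by ``protein/env_start-env_end``). Families failing the eligibility
    thresholds, or without an alignment, are skipped. Permutation streams
    are drawn from one seeded generator in sorted family order, so results
    are reproducible for a fixed seed regardless of input ordering.
    """
    deduped = dedupe_sites(sites, proteome, exempt_species=exempt_species)
    instances = map_sites_to_domains(deduped, domains, proteome)
    kwargs = {}
    if min_instances is not None:
        kwargs["min_instances"] = min_instances
    if min_sites is not None:
        kwargs["min_sites"] = min_sites
    eligible = [
        f for f in select_families(instances, **kwargs) if f in alignment_rows
    ]
    grouped = group_by_family(instances)

    rng = np.random.default_rng(params.rng_seed)
    alignments: dict[str, FamilyAlignment] = {}
    profiles: dict[str, PositionProfile] = {}
    for family_id in sorted(eligible):
        aln = project_to_alignment(
            grouped[family_id], alignment_rows[family_id], family_id=family_id
        )
        alignments[family_id] = aln
        profiles[family_id] = family_profile(aln, params, rng)
    regions, threshold, n_tests = call_hotspots(profiles, params)
    return DetectionResult(
        params=params,
        eligible_families=sorted(eligible),
        alignments=alignments,
        profiles=profiles,
        regions=regions,
        threshold=threshold,
        n_tests=n_tests,
    )


def run_manifest(
    params: HotspotParams, input_paths: Mapping[str, str | Path]
) -> dict:
    """Provenance record: parameters, seed and SHA-256 of every input."""
    hashes = {}
    for name, p in sorted(input_paths.items()):
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        hashes[name] = digest
    return {"parameters": asdict(params), "input_sha256": hashes}


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
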
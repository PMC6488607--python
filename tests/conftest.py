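from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phosfam.io_formats import ProteinRecord
from phosfam.site_mapping import DomainInstance, FamilyAlignment, project_to_alignment

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_alignment(
    gapped_rows: dict[str, str],
    site_locals: dict[str, list[int]],
    family_id: str = "FAM",
) -> FamilyAlignment:
    """Assemble a FamilyAlignment from plain gapped rows and 1-based local
    site positions (the residue is read off the sequence)."""
    instances = []
    rows = {}
    for name, gapped in gapped_rows.items():
        seq = gapped.replace("-", "")
        rid = f"{name}/1-{len(seq)}"
        rows[rid] = gapped
        sites = tuple((loc, seq[loc - 1]) for loc in site_locals.get(name, []))
        instances.append(
            DomainInstance(
                family_id=family_id,
                protein_id=name,
                env_start=1,
                env_end=len(seq),
                sequence=seq,
                sites_local=sites,
            )
        )
    return project_to_alignment(instances, rows, family_id=family_id)


@pytest.fixture
def tiny_proteome() -> list[ProteinRecord]:
    return [
        ProteinRecord("p1", "MKSAATYLNN", "yeast"),
        ProteinRecord("p2", "MKSAATYLNQ", "yeast"),
        ProteinRecord("p3", "GGSGG", "yeast"),
    ]


@pytest.fixture
def site_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": ["p1", "p1", "p2"],
            "position": [3, 6, 7],
            "residue": ["S", "T", "Y"],
            "species": ["yeast"] * 3,
            "source": ["lab"] * 3,
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
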
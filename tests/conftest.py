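import numpy as np
import pandas as pd
import pytest

from fenflux import PhylotypeTable, VesselSpec


@pytest.fixture
def study_vessel() -> VesselSpec:
    """The incubation tube of the study design: 27 ml total, 10 ml liquid
    (9.5 ml after first sampling), 15 degC."""
    return VesselSpec()


def make_phylotype_table(
    counts: dict[str, list[int]],
    treatments: dict[str, str],
    markers: dict[str, str] | None = None,
    feature_meta: pd.DataFrame | None = None,
) -> PhylotypeTable:
    """Small helper: counts maps sample id -> per-feature counts."""
    df = pd.DataFrame(counts)
    df.index = [f"PT{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {
            "marker": {
                s: (markers or {}).get(s, "rRNA") for s in df.columns
            },
            "treatment": treatments,
            "replicate": {s: i + 1 for i, s in enumerate(df.columns)},
        }
    )
    meta.index.name = "sample_id"
    return PhylotypeTable(counts=df, sample_meta=meta, feature_meta=feature_meta)


@pytest.fixture
def two_class_table() -> PhylotypeTable:
    """3 vs 3 rRNA samples with one strongly enriched feature (PT0)."""
    rng = np.random.default_rng(42)
    base = np.array([50, 500, 2000, 800, 120], dtype=float)
    counts = {}
    treatments = {}
    for i in range(3):
        v = rng.poisson(base)
        counts[f"SU{i+1}"] = v.tolist()
        treatments[f"SU{i+1}"] = "SU"
    for i in range(3):
        v = rng.poisson(base * np.array([8.0, 1, 1, 1, 1]))
        counts[f"SH{i+1}"] = v.tolist()
        treatments[f"SH{i+1}"] = "SH"
    return make_phylotype_table(counts, treatments)
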
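import numpy as np
import pandas as pd
import pytest

from clicktrace.feature_io import FeatureTable


def make_manifest(samples):
    """samples: list of (sample_id, condition, group)."""
    df = pd.DataFrame(samples, columns=["sample_id", "condition", "group"])
    df["replicate"] = df.groupby("condition").cumcount() + 1
    return df.set_index("sample_id")


def make_table(features, manifest, ms2=None):
    """features: list of (feature_id, mz, rt, {sample: intensity})."""
    feat = pd.DataFrame(
        [(f[0], f[1], f[2]) for f in features], columns=["feature_id", "mz", "rt"]
    ).set_index("feature_id")
    intens = pd.DataFrame.from_dict(
        {f[0]: f[3] for f in features}, orient="index"
    ).reindex(index=feat.index, columns=list(manifest.index))
    return FeatureTable(
        features=feat.astype(float),
        intensities=intens.astype(float),
        manifest=manifest,
        ms2=ms2 or {},
    )


@pytest.fixture
def three_condition_manifest():
    return make_manifest(
        [(f"{c}{i}", c, "") for c in ("PC", "NC", "NT") for i in (1, 2, 3)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
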
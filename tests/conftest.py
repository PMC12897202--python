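import warnings

import numpy as np
import pytest

from mitotexture import preprocess_image, synthgen
from mitotexture.features import FeatureTable, extract_all

# study conditions for the synthetic benchmark: 30 ROIs per class, default
# (moderate) noise, one fixed seed
BENCH_SEED = 11
BENCH_N_PER_CLASS = 30


@pytest.fixture(scope="session")
def bench_rois():
    """The 30/30/30 fiber/puncta/rod benchmark ROI set."""
    rois, manifest = synthgen.make_dataset(
        BENCH_N_PER_CLASS, synthgen.SynthConfig(seed=BENCH_SEED), seed=BENCH_SEED)
    return rois, manifest


@pytest.fixture(scope="session")
def bench_table_raw(bench_rois) -> FeatureTable:
    """93-feature table of the raw (unpreprocessed) benchmark ROIs."""
    rois, manifest = bench_rois
    rows = [extract_all(r.image, roi_id=rec["roi_id"], class_label=rec["class_label"])
            for r, rec in zip(rois, manifest.to_dict("records"))]
    return FeatureTable(rows)


@pytest.fixture(scope="session")
def bench_table_preprocessed(bench_rois) -> FeatureTable:
    """93-feature table after the full pre-processing chain."""
    rois, manifest = bench_rois
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows = [extract_all(preprocess_image(r.image), roi_id=rec["roi_id"],
                            class_label=rec["class_label"])
                for r, rec in zip(rois, manifest.to_dict("records"))]
    return FeatureTable(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
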
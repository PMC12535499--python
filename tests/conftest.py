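import numpy as np
import pytest

from mzlipid import FeatureRecord, FeatureTable, GradientProgram, TaxonomyMap


@pytest.fixture
def program() -> GradientProgram:
    """The reference 20 -> 80 %A over 13 min program."""
    return GradientProgram()


def make_record(fid="F1", mz=150.0, rt=5.0, polarity="negative", **kw) -> FeatureRecord:
    return FeatureRecord(feature_id=fid, mz=mz, rt_min=rt, polarity=polarity, **kw)


@pytest.fixture
def toy_table() -> FeatureTable:
    """Five features spanning both polarities, identified and not."""
    return FeatureTable(
        (
            make_record("F1", 150.0, 2.0, "negative", hmdb_id="HMDB0000001"),
            make_record("F2", 550.0, 1.5, "positive", hmdb_id="HMDB0000002"),
            make_record("F3", 90.0, 7.0, "negative"),
            make_record("F4", 720.0, 12.0, "positive", hmdb_id="HMDB0000003",
                        annotation="palmitate-like"),
            make_record("F5", 320.0, 9.5, "negative"),
        ),
        provenance="toy",
    )


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "HMDB0000001": "Organic acids and derivatives",
            "HMDB0000002": "Lipids and lipid-like molecules",
            "HMDB0000003": "Lipids and lipid-like molecules",
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)
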
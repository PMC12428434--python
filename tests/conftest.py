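import warnings

import pytest

from mitocr import genome_model as gm


@pytest.fixture(scope="session")
def reference_record():
    """The packaged feature table (advisory-column warnings silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", gm.FeatureTableWarning)
        return gm.load_reference_feature_table()
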
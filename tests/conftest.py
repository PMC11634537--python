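import pytest

import _util


@pytest.fixture
def worked_example():
    """The worked single-duplication 11-leaf multi-copy tree, tagged."""
    return _util.worked_example_tagged()


@pytest.fixture
def prefix_mapping():
    return _util.PREFIX_MAPPING
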
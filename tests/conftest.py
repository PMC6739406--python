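import json

import pytest

from xcimir import pipeline, synth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One frozen synthetic bundle shared by the whole session."""
    d = tmp_path_factory.mktemp("paper_fixture")
    synth.paper_fixture(d, seed=17)
    return d


@pytest.fixture(scope="session")
def fixture_manifest(fixture_dir):
    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def fixture_report(fixture_dir):
    """Full pipeline run on the frozen bundle."""
    return pipeline.run_all(pipeline.RunConfig.for_fixture(str(fixture_dir)))
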
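import pytest
from hypothesis import settings

from srameta import schema

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from srameta.lexicons import load_default_lexicons
from srameta.pipeline import write_fixture_dir
from srameta.synthetic import generate_pool


@pytest.fixture(scope="session")
def registry():
    return schema.registry()


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


@pytest.fixture(scope="session")
def small_pool(lexicons):
    """30 synthetic samples covering all 15 reconstructed classes."""
    return generate_pool(30, seed=11, config={"lexicons": lexicons})


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_pool):
    """Offline fixture directory rendered from the small pool."""
    directory = tmp_path_factory.mktemp("fixtures")
    return write_fixture_dir(small_pool, directory)


RUN_XML = """<EXPERIMENT_PACKAGE>
  <STUDY accession="SRP900001">
    <DESCRIPTOR>
      <STUDY_TITLE>Melanoma cohort</STUDY_TITLE>
      <STUDY_ABSTRACT>RNA profiling of melanoma biopsies.</STUDY_ABSTRACT>
    </DESCRIPTOR>
  </STUDY>
  <SAMPLE accession="SRS900001">
    <TITLE>patient tumor</TITLE>
    <SAMPLE_LINKS>
      <XREF_LINK><DB>biosample</DB><ID>SAMN00000001</ID></XREF_LINK>
    </SAMPLE_LINKS>
    <SAMPLE_ATTRIBUTES>
      <SAMPLE_ATTRIBUTE><TAG>tissue</TAG><VALUE>skin</VALUE></SAMPLE_ATTRIBUTE>
    </SAMPLE_ATTRIBUTES>
  </SAMPLE>
  <EXPERIMENT accession="SRX900001"/>
  <RUN accession="SRR900001"/>
</EXPERIMENT_PACKAGE>
"""

BIOSAMPLE_XML = """<BioSample accession="SAMN00000001">
  <Attributes>
    <Attribute attribute_name="tissue">lung</Attribute>
    <Attribute attribute_name="sex">F</Attribute>
    <Attribute attribute_name="age">42</Attribute>
  </Attributes>
</BioSample>
"""


@pytest.fixture
def run_xml():
    return RUN_XML


@pytest.fixture
def biosample_xml():
    return BIOSAMPLE_XML
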
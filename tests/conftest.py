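import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from walkernel import SynthConfig, build_instances, generate_synthetic_corpus
from walkernel.path_extract import PathString

#: Hand-written two-sentence fixture in the unified PPI XML dialect.
#: charOffsets are inclusive, as in the converted corpora.
UNIFIED_XML_FIXTURE = """<?xml version="1.0" encoding="utf-8"?>
<corpus source="fixture">
  <document id="d1">
    <sentence id="d1.s0" text="ProtA binds ProtB .">
      <entity id="d1.s0.e0" charOffset="0-4" type="protein" text="ProtA"/>
      <entity id="d1.s0.e1" charOffset="12-16" type="protein" text="ProtB"/>
      <interaction e1="d1.s0.e0" e2="d1.s0.e1" directed="true"/>
      <sentenceanalyses>
        <tokenizations><tokenization>
          <token id="t_1" text="ProtA" POS="NN" charOffset="0-4"/>
          <token id="t_2" text="binds" POS="VBZ" charOffset="6-10"/>
          <token id="t_3" text="ProtB" POS="NN" charOffset="12-16"/>
          <token id="t_4" text="." POS="." charOffset="18-18"/>
        </tokenization></tokenizations>
        <parses><parse>
          <dependency id="dep_0" t1="t_2" t2="t_1" type="nsubj"/>
          <dependency id="dep_1" t1="t_2" t2="t_3" type="dobj"/>
          <dependency id="dep_2" t1="t_2" t2="t_4" type="punct"/>
        </parse></parses>
      </sentenceanalyses>
    </sentence>
    <sentence id="d1.s1" text="It is unknown .">
      <sentenceanalyses>
        <tokenizations><tokenization>
          <token id="t_1" text="It" POS="PRP" charOffset="0-1"/>
          <token id="t_2" text="is" POS="VBZ" charOffset="3-4"/>
          <token id="t_3" text="unknown" POS="JJ" charOffset="6-12"/>
          <token id="t_4" text="." POS="." charOffset="14-14"/>
        </tokenization></tokenizations>
        <parses><parse>
          <dependency id="dep_0" t1="t_2" t2="t_1" type="nsubj"/>
          <dependency id="dep_1" t1="t_2" t2="t_3" type="acomp"/>
          <dependency id="dep_2" t1="t_2" t2="t_4" type="punct"/>
        </parse></parses>
      </sentenceanalyses>
    </sentence>
  </document>
</corpus>
"""

#: Hand-written LLL-05 tuple-format fixture: one sentence with a directed
#: gold pair, one with no annotation at all.
LLL_FIXTURE = """ID\tlll.1
sentence\tsigK activates cotD transcription
words\tword(0,'sigK',0,3), word(1,'activates',5,13), word(2,'cotD',15,18), word(3,'transcription',20,32)
syntactic_relations\trelation('subj',1,0), relation('obj',1,3), relation('mod_att',3,2)
agents\tagent(0)
targets\ttarget(2)
genic_interactions\tgenic_interaction(0,2)

ID\tlll.2
sentence\tsigB is expressed
words\tword(0,'sigB',0,3), word(1,'is',5,6), word(2,'expressed',8,16)
syntactic_relations\trelation('subj',2,0), relation('aux',2,1)
"""


@pytest.fixture
def xml_fixture_path(tmp_path):
    path = tmp_path / "fixture.xml"
    path.write_text(UNIFIED_XML_FIXTURE)
    return path


@pytest.fixture
def lll_fixture_path(tmp_path):
    path = tmp_path / "fixture.lll"
    path.write_text(LLL_FIXTURE)
    return path


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_synthetic_corpus(
        SynthConfig(n_docs=10, sentences_per_doc=4, nesting_rate=0.2, seed=11)
    )


@pytest.fixture(scope="session")
def small_instances(small_corpus):
    return build_instances(small_corpus)


def make_path_string(rng, n_symbols, alphabet=("a", "b", "c", "d")):
    """Random path-shaped string: odd length, alternating node/edge roles.

    Edge symbols get a direction suffix so the node and edge alphabets are
    disjoint, as they are in real path strings.
    """
    assert n_symbols % 2 == 1
    symbols, roles = [], []
    for i in range(n_symbols):
        if i % 2 == 0:
            symbols.append(rng.choice(alphabet))
            roles.append("n")
        else:
            symbols.append(rng.choice(alphabet) + rng.choice(["(UP)", "(DN)"]))
            roles.append("e")
    return PathString(tuple(symbols), tuple(roles), "lexical")
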
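"""Shared fixtures: tiny hand-written BioPAX Turtle knowledge bases."""

import pytest
import rdflib

from paxnet.kb_access import BP, KnowledgeBase

PREFIX = f"@prefix bp: <{BP}> .\n@prefix ex: <http://example.org/kb/> .\n"

# Exactly 7 triples: one protein and one regulation interaction skeleton.
TINY_TTL = PREFIX + """
ex:reg1 a bp:TemplateReactionRegulation ;
    bp:controlled ex:tmpl1 ;
    bp:controller ex:X .
ex:tmpl1 a bp:TemplateReaction ;
    bp:product ex:A .
ex:X a bp:Protein ;
    bp:displayName "X" .
"""

# One complete planted regulation: X --ACTIVATION--> A, source "ctd";
# plus a second one Y --INHIBITION--> A from source "pid".
REGULATION_TTL = PREFIX + """
ex:reg1 a bp:TemplateReactionRegulation ;
    bp:controlled ex:tmpl1 ;
    bp:controller ex:X ;
    bp:controlType "ACTIVATION" ;
    bp:dataSource ex:src-ctd .
ex:tmpl1 a bp:TemplateReaction ;
    bp:product ex:A .
ex:reg2 a bp:TemplateReactionRegulation ;
    bp:controlled ex:tmpl2 ;
    bp:controller ex:Y ;
    bp:controlType "INHIBITION" ;
    bp:dataSource ex:src-pid .
ex:tmpl2 a bp:TemplateReaction ;
    bp:product ex:A .
ex:X a bp:Protein ; bp:displayName "X" .
ex:Y a bp:Protein ; bp:displayName "Y" .
ex:A a bp:Protein ; bp:displayName "A" .
ex:src-ctd a bp:Provenance ; bp:displayName "ctd" .
ex:src-pid a bp:Provenance ; bp:displayName "pid" .
"""

# Kinase K catalyzes a reaction converting P0 into P (signaling pattern).
SIGNALING_TTL = PREFIX + """
ex:cat1 a bp:Catalysis ;
    bp:controlled ex:rxn1 ;
    bp:controller ex:K ;
    bp:controlType "ACTIVATION" ;
    bp:dataSource ex:src-pid .
ex:rxn1 a bp:BiochemicalReaction ;
    bp:left ex:P0 ;
    bp:right ex:P .
ex:K a bp:Protein ; bp:displayName "K" .
ex:P0 a bp:Protein ; bp:displayName "P0" .
ex:P a bp:Protein ; bp:displayName "P" .
ex:src-pid a bp:Provenance ; bp:displayName "pid" .
"""

# One TemplateReactionRegulation AND one Catalysis on the same target "A":
# used to check that the two query patterns stay separated.
MIXED_TTL = PREFIX + """
ex:reg1 a bp:TemplateReactionRegulation ;
    bp:controlled ex:tmpl1 ;
    bp:controller ex:TF ;
    bp:controlType "ACTIVATION" ;
    bp:dataSource ex:src-ctd .
ex:tmpl1 a bp:TemplateReaction ; bp:product ex:A .
ex:cat1 a bp:Catalysis ;
    bp:controlled ex:rxn1 ;
    bp:controller ex:K ;
    bp:controlType "INHIBITION" ;
    bp:dataSource ex:src-pid .
ex:rxn1 a bp:BiochemicalReaction ; bp:right ex:A .
ex:TF a bp:Protein ; bp:displayName "TF" .
ex:K a bp:Protein ; bp:displayName "K" .
ex:A a bp:Protein ; bp:displayName "A" .
ex:src-ctd a bp:Provenance ; bp:displayName "ctd" .
ex:src-pid a bp:Provenance ; bp:displayName "pid" .
"""

GENE_INFO = (
    "#tax_id\tGeneID\tSymbol\tSynonyms\n"
    "9606\t7157\tTP53\tP53|LFS1\n"
    "9606\t4609\tMYC\tc-Myc|bHLHe39\n"
    "9606\t999\tAMBIG\tSHARED\n"
    "9606\t998\tAMBIG2\tSHARED\n"
    "9606\t1\tNOSYN\t-\n"
)


def kb_from_ttl(text: str) -> KnowledgeBase:
    graph = rdflib.Graph()
    graph.parse(data=text, format="turtle")
    return KnowledgeBase(graph=graph)


@pytest.fixture
def tiny_kb():
    return kb_from_ttl(TINY_TTL)


@pytest.fixture
def regulation_kb():
    return kb_from_ttl(REGULATION_TTL)


@pytest.fixture
def signaling_kb():
    return kb_from_ttl(SIGNALING_TTL)


@pytest.fixture
def mixed_kb():
    return kb_from_ttl(MIXED_TTL)


@pytest.fixture
def tiny_ttl_file(tmp_path):
    path = tmp_path / "tiny.ttl"
    path.write_text(TINY_TTL)
    return str(path)


@pytest.fixture
def gene_info_file(tmp_path):
    path = tmp_path / "gene_info.tsv"
    path.write_text(GENE_INFO)
    return str(path)
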
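import pytest
from hypothesis import settings

from ontoxref.model import Ontology, OntologyTerm, normalize_xref

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

CKD_OBO = """\
format-version: 1.2

[Term]
id: MONDO:0005300
name: chronic kidney disease
xref: MeSH:D007676
xref: UMLS:C0022661
xref: EFO:EFO_0003884
xref: NCIT:C80078
xref: DOID:784
xref: ICD10:N18.9

[Term]
id: MONDO:0005240
name: kidney disorder
"""

CKD_MEMBERS = {
    "MESH": "D007676",
    "UMLS": "C0022661",
    "EFO": "EFO_0003884",
    "NCIT": "NCIT_C80078",
    "DOID": "DOID_784",
    "ICD10": "N18.9",
}


def make_ontology(namespace, terms):
    """Build an Ontology from {id: (label, parents, xrefs, obsolete, replaced_by)}.

    Shorter tuples fall back to defaults; xrefs are raw strings like
    ``"UMLS:C0022661"``.
    """
    ontology = Ontology(namespace=namespace)
    for local_id, fields in terms.items():
        fields = tuple(fields) + ("", (), (), False, None)[len(fields):]
        label, parents, xrefs, obsolete, replaced_by = fields
        ontology.add(
            OntologyTerm(
                ontology=namespace,
                local_id=local_id,
                label=label,
                parents=set(parents),
                xrefs={normalize_xref(x) for x in xrefs},
                obsolete=obsolete,
                replaced_by=replaced_by,
            )
        )
    return ontology


@pytest.fixture
def ckd_mondo():
    from ontoxref.model import parse_obo_subset

    return parse_obo_subset(CKD_OBO, "MONDO")
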
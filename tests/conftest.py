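import io

import pandas as pd
import pytest

from stressprio.ontology import OntologyRegistry, parse_obo

DROUGHT_OBO = """\
format-version: 1.2
ontology: go

[Term]
id: GO:0006950
name: response to stress

[Term]
id: GO:0009414
name: response to water deprivation
is_a: GO:0006950

[Term]
id: GO:0009269
name: response to desiccation
is_a: GO:0009414

[Term]
id: GO:0009819
name: drought recovery
is_a: GO:0006950
"""

EO_OBO = """\
format-version: 1.2
ontology: eo

[Term]
id: EO:0007000
name: plant environment regimen

[Term]
id: EO:0007404
name: drought environment
is_a: EO:0007000
"""

GRO_OBO = """\
format-version: 1.2
ontology: gro

[Term]
id: GRO:0007148
name: booting stage

[Term]
id: GRO:0007150
name: late-booting stage
is_a: GRO:0007148
"""


@pytest.fixture(scope="session")
def go_graph():
    return parse_obo(DROUGHT_OBO)["GO"]


@pytest.fixture(scope="session")
def registry():
    return OntologyRegistry.from_obo(DROUGHT_OBO, EO_OBO, GRO_OBO)


@pytest.fixture()
def assoc_table(registry):
    """Small direct association table spanning GO/EO/GRO, pre-propagation."""
    from stressprio.associations import read_associations

    tsv = "\n".join([
        "gene_id\tspecies\tterm_id\tontology_key",
        "Sb_a\tsorghum\tGO:0009269\tGO",
        "Sb_a\tsorghum\tEO:0007404\tEO",
        "Sb_b\tsorghum\tGO:0009414\tGO",
        "Os_r1\trice\tEO:0007404\tEO",
        "Sb03g003110\tsorghum\tGRO:0007150\tGRO",
        "",
    ])
    return read_associations(io.StringIO(tsv))
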
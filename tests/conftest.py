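import os

import pytest

from phylograft.pipeline import cmd_run, load_run_config
from phylograft.synthetic import build_verification_case, generate_taxonomy, write_fixture_dir

CONFIG_INI = """\
[paths]
tree = tree.nwk
alignment = alignment.fasta
otu_map = otu_map.tsv
taxonomy = taxonomy.tsv
db = db.fasta
ingroup = ingroup.txt
workdir = work

[run]
seed = 1
"""


@pytest.fixture(scope="session")
def tax15():
    """1 root + 2 genera + 12 species = 15 records."""
    return generate_taxonomy(2, 6, seed=1)


@pytest.fixture(scope="session")
def verification_case():
    return build_verification_case(seed=1)


@pytest.fixture(scope="session")
def verification_run(tmp_path_factory, verification_case):
    """Full default-config pipeline run on the verification fixture, shared
    across tests. Returns (fixture_dir, workdir, result, case)."""
    root = tmp_path_factory.mktemp("verification")
    write_fixture_dir(verification_case, root)
    ini = root / "config.ini"
    ini.write_text(CONFIG_INI)
    config = load_run_config(ini)
    result = cmd_run(config)
    return str(root), config.workdir, result, verification_case
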
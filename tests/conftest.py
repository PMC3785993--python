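import pytest

import frailtymap as fm


@pytest.fixture(scope="session")
def schema():
    return fm.canonical_schema()


@pytest.fixture(scope="session")
def table_stack():
    return fm.table_pattern_fixture()


@pytest.fixture(scope="session")
def resolved_table_stack(table_stack):
    return fm.normalize_units(fm.resolve_kept_values(table_stack))
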
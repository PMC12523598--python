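import pytest

from bracketqc.reference_data import (
    assignments_from_table,
    load_plan_assignments,
    load_sigma_table,
)


@pytest.fixture(scope="session")
def sigma_table():
    return load_sigma_table()


@pytest.fixture(scope="session")
def plan_assignment_table():
    return load_plan_assignments()


@pytest.fixture(scope="session")
def plan_assignments(plan_assignment_table):
    return assignments_from_table(plan_assignment_table)
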
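import pytest

from trialbf import packaged_subgroup_table, read_subgroup_table


@pytest.fixture(scope="session")
def fixture_path():
    return str(packaged_subgroup_table())


@pytest.fixture(scope="session")
def fixture_rows(fixture_path):
    return read_subgroup_table(fixture_path)


@pytest.fixture(scope="session")
def diffuse_row(fixture_rows):
    (row,) = [r for r in fixture_rows if r.subgroup == "Diffuse malignant"]
    return row


# Published results table: (category, subgroup) -> (BF10, P10 %)
PUBLISHED_RESULTS = {
    ("MAO-B inhibitor", "Yes"): (0.44, 30.75),
    ("MAO-B inhibitor", "No"): (0.13, 11.66),
    ("Hoehn and Yahr stage", "2"): (0.69, 40.90),
    ("Hoehn and Yahr stage", "1"): (0.44, 30.65),
    ("RBDSQ", ">=5"): (0.33, 24.59),
    ("RBDSQ", "<5"): (0.14, 12.51),
    ("Data-driven subphenotype", "Diffuse malignant"): (1.17, 53.92),
    ("Data-driven subphenotype", "Nondiffuse malignant"): (0.13, 11.11),
}
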
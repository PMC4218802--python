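import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metaratio.annotation import AnnotationRecord, Library, normalize_lineage
from metaratio.catalog import default_catalog
from metaratio.matrices import TaxonFunctionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    read_id="r1",
    library_id="B_DNA",
    molecule="DNA",
    genus="Synechococcus",
    species="sp001",
    phylum="Cyanobacteria",
    function_label="RuBisCo",
    bit_score=120.0,
    e_value=1e-20,
    align_len_aa=40,
    read_len_bp=None,
    domain="Bacteria",
):
    return AnnotationRecord(
        read_id=read_id,
        library_id=library_id,
        molecule=molecule,
        lineage=normalize_lineage([domain, phylum, "", "", "", genus, species]),
        function_label=function_label,
        bit_score=bit_score,
        e_value=e_value,
        align_len_aa=align_len_aa,
        read_len_bp=read_len_bp,
    )


def make_library(records, library_id="B_DNA", molecule="DNA"):
    return Library(library_id=library_id, molecule=molecule, records=list(records))


def matrix_from_frame(df, rank="species", library_id="B_DNA", molecule="DNA"):
    return TaxonFunctionMatrix(
        rank=rank,
        counts=df.astype("int64"),
        library_id=library_id,
        molecule=molecule,
    )


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def toy_library():
    """4 records: (A, g1), (A, g1), (B, g1), (B, g2)."""
    recs = [
        make_record(read_id=f"r{i}", genus=genus, species="sp1", function_label=fn)
        for i, (genus, fn) in enumerate([("A", "g1"), ("A", "g1"), ("B", "g1"), ("B", "g2")])
    ]
    return make_library(recs)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        {"g1": [2, 1], "g2": [0, 1]}, index=["A sp1", "B sp1"]
    ).astype("int64")
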
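import numpy as np
import pandas as pd
import pytest

from cbrel.ages import parse_age
from cbrel.io import ExpressionDataset, SpecimenRecord, StructureLabel


def build_dataset(
    genes,
    columns,
    values,
    ages,
    cerebellar_labels=frozenset({"CB", "CBC"}),
):
    """Assemble an ExpressionDataset from explicit parts.

    ``columns`` is a list of (donor_id, structure) pairs, ``values`` a
    genes x columns array (NaN = missing sample), ``ages`` a donor ->
    age-label mapping.
    """
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=pd.Index(list(genes), name="gene"),
        columns=pd.MultiIndex.from_tuples(columns, names=["donor_id", "structure"]),
    )
    specimens = []
    seen = []
    for donor, _ in columns:
        if donor not in seen:
            seen.append(donor)
    for donor in seen:
        structs = tuple(
            StructureLabel(s, s in cerebellar_labels) for d, s in columns if d == donor
        )
        specimens.append(SpecimenRecord(donor, parse_age(ages[donor]), structs))
    return ExpressionDataset(df, specimens, frozenset(cerebellar_labels))


@pytest.fixture
def four_region_dataset():
    """Three genes, two donors, cerebellum + three other regions each."""
    columns = [
        (d, s) for d in ("D1", "D2") for s in ("CBC", "DFC", "HIP", "AMY")
    ]
    rng = np.random.default_rng(7)
    values = rng.lognormal(0.0, 0.5, (3, len(columns)))
    return build_dataset(
        ["ATM", "G1", "G2"], columns, values, {"D1": "12 pcw", "D2": "3 yrs"}
    )
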
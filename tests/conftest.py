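import numpy as np
import pandas as pd
import pytest

from hitswitch.cohort_io import AlterationMatrix, DriverCatalog


@pytest.fixture
def toy_matrix() -> AlterationMatrix:
    """6 samples × 2 genes: GA exercises the loss-mode masking rule
    (CN states 0,0,-1,-1,+1,-2 with muts 0,1,0,1,1,1); GB is a plain
    mutation partner."""
    mut = np.array(
        [[0, 0], [1, 0], [0, 1], [1, 1], [1, 0], [1, 1]], dtype=np.uint8
    )
    cn = np.array(
        [[0, 0], [0, 0], [-1, 0], [-1, 0], [1, 0], [-2, 0]], dtype=np.int8
    )
    return AlterationMatrix(
        cancer_type="TOY",
        samples=tuple(f"s{i}" for i in range(6)),
        genes=("GA", "GB"),
        mut=mut,
        cn=cn,
    )


@pytest.fixture
def toy_catalog() -> DriverCatalog:
    return DriverCatalog(
        pd.DataFrame(
            {
                "gene": ["GA", "GB", "GC"],
                "cancer_type": ["TOY", "TOY", "OTHER"],
                "role": ["TSG", "OG", "unassigned"],
            }
        )
    )


@pytest.fixture
def maf_file(tmp_path):
    rows = [
        ("TP53", "S1", "Nonsense_Mutation", "", "", "LUAD"),
        ("TP53", "S2", "Missense_Mutation", "deleterious(0.01)", "benign(0.1)", "LUAD"),
        ("KRAS", "S2", "Missense_Mutation", "tolerated(0.6)", "benign(0.2)", "LUAD"),
        ("EGFR", "S3", "In_Frame_Del", "", "", "LUAD"),
        ("TP53", "S3", "Silent", "", "", "LUAD"),
        ("BRAF", "S1", "Frame_Shift_Ins", "", "", "LUAD"),
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "SIFT",
            "PolyPhen",
            "Cancer_Type",
        ],
    )
    path = tmp_path / "mutations.maf"
    frame.to_csv(path, sep="\t", index=False)
    return path
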
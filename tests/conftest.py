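import numpy as np
import pandas as pd
import pytest

from c2dx import CohortSpec, GenePanel, Platform, Role, generate_cohort


@pytest.fixture
def tiny_panel() -> GenePanel:
    """Two diagnostic genes (one per subtype) plus two housekeeping genes."""
    return GenePanel(
        [
            ("ADg1", Role.LUAD),
            ("SQg1", Role.LUSC),
            ("HK1", Role.HOUSEKEEPING),
            ("HK2", Role.HOUSEKEEPING),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic labeled count cohort with its ground truth."""
    spec = CohortSpec(n_luad=20, n_lusc=12, n_nos=5, seed=42)
    return generate_cohort(spec)


@pytest.fixture
def rcc_text() -> str:
    return (
        "<Header>\n"
        "FileVersion,1.7\n"
        "</Header>\n"
        "<Sample_Attributes>\n"
        "ID,FNA_demo\n"
        "</Sample_Attributes>\n"
        "<Code_Summary>\n"
        "CodeClass,Name,Accession,Count\n"
        "Endogenous,TP63,NM_003722.4,100\n"
        "Endogenous,TMC5,NM_024780.3,50\n"
        "Housekeeping,ACTB,NM_001101.3,2000\n"
        "Positive,POS_A(128),ERCC_00117.1,8000\n"
        "Negative,NEG_B(0),ERCC_00096.1,3\n"
        "</Code_Summary>\n"
    )


@pytest.fixture
def random_expression_matrix():
    """Factory for random non-negative matrices on a given gene index."""

    def make(genes, n_samples, seed=0, platform=Platform.COUNTS):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 5000, size=(len(genes), n_samples)).astype(float)
        from c2dx import ExpressionMatrix

        return ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=pd.Index(genes, name="gene"),
                columns=[f"S{i:03d}" for i in range(n_samples)],
            ),
            platform=platform,
        )

    return make
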
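import numpy as np
import pandas as pd
import pytest

from vepbench.types import (
    MutationRecord,
    PatientRecord,
    ScoreMatrix,
)


@pytest.fixture
def toy_mutations():
    """Eight-patient toy cohort used by the mutual-exclusivity fixture.

    Two patients carry a pathogenic-classified KEAP1 VUS and no pathway
    oncogenic mutation; one carries both; three carry only a pathway
    oncogenic mutation; two carry neither.
    """
    muts = []

    def vus(pid, gene, pchange):
        muts.append(
            MutationRecord(
                patient_id=pid,
                sample_id=pid + "s",
                gene=gene,
                protein_change=pchange,
                is_missense=True,
                oncokb_class="vus",
            )
        )

    def onco(pid, gene, pchange):
        muts.append(
            MutationRecord(
                patient_id=pid,
                sample_id=pid + "s",
                gene=gene,
                protein_change=pchange,
                is_missense=True,
                oncokb_class="oncogenic",
            )
        )

    vus("p1", "KEAP1", "p.R320Q")
    vus("p2", "KEAP1", "p.R320Q")
    vus("p3", "KEAP1", "p.G333C")
    onco("p3", "NFE2L2", "p.E79Q")
    onco("p4", "NFE2L2", "p.E79Q")
    onco("p5", "CUL3", "p.S53L")
    onco("p6", "KEAP1", "p.G480W")
    return muts


@pytest.fixture
def toy_patients():
    return [
        PatientRecord(
            patient_id=f"p{i}",
            t_dx=0.0,
            t_entry=1.0,
            t_end=12.0 + i,
            event=i % 2 == 0,
            tmb=5.0,
            msi_score=1.0,
        )
        for i in range(1, 9)
    ]


@pytest.fixture
def small_scores():
    frame = pd.DataFrame(
        {
            "m1": [0.9, 0.8, 0.2, np.nan],
            "m2": [0.7, np.nan, 0.1, np.nan],
        },
        index=pd.Index(
            ["G1:p.A1V", "G1:p.C2F", "G2:p.D3E", "G2:p.E4K"], name="variant_key"
        ),
    )
    return ScoreMatrix(frame)
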
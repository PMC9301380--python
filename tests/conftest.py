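import pandas as pd
import pytest

from cdr3delta import Clonotype, RepertoireSample, load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()


def make_clonotype(junction_nt, junction_aa, read_count, sample_id="S1", donor_id="D01",
                   replicate_id="r1", subset_label="CD27pos", v_call="TRDV2*01",
                   j_call="TRDJ1*01", d_call="", productive=True):
    return Clonotype(
        junction_nt=junction_nt,
        junction_aa=junction_aa,
        v_call=v_call,
        j_call=j_call,
        d_call=d_call,
        read_count=read_count,
        sample_id=sample_id,
        donor_id=donor_id,
        replicate_id=replicate_id,
        subset_label=subset_label,
        productive=productive,
    )


def make_sample(clonotypes, sample_id="S1", donor_id="D01", replicate_id="r1",
                subset_label="CD27pos", sorted_cell_count=50_000):
    return RepertoireSample(
        sample_id=sample_id,
        donor_id=donor_id,
        replicate_id=replicate_id,
        subset_label=subset_label,
        sorted_cell_count=sorted_cell_count,
        clonotypes=tuple(clonotypes),
    )


@pytest.fixture
def toy_sample():
    """Three clonotypes with read counts 5, 1 and 2 in one sample."""
    ref_junction = "TGTGCCTGTGACACCCTGGGGGATACCGATAAACTCATCTTT"  # CACDTLGDTDKLIF
    return make_sample(
        [
            make_clonotype(ref_junction, "CACDTLGDTDKLIF", 5),
            make_clonotype("TGTGCCTGTGACACCGTGGGGGATACCGATAAACTCATCTTT", "CACDTVGDTDKLIF", 1),
            make_clonotype("TGTGCCTGTGACACCATTGGGGATACCGATAAACTCATCTTT", "CACDTIGDTDKLIF", 2),
        ]
    )
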
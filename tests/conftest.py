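"""Shared fixtures: enzyme table, synthetic plasmids, and experiment folders."""

import pytest

from cfsim.dna import Chem, Polynucleotide, Protrusion
from cfsim.enzymes import default_table
from cfsim.fixtures import make_random_dna, make_primer_pair, write_experiment_folder


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def fig2_style_substrate():
    """Linear dsDNA previously cut with BamHI (then dephosphorylated) and
    XmaI, carrying one internal EcoRI site: the canonical two-fragment
    digestion scenario."""
    core = make_random_dna(
        200, seed=209,
        required_sites=[("GAATTC", 100)],
        forbidden_patterns=["GGATCC", "CCCGGG"],
    ).sequence
    return Polynucleotide(
        sequence=core,
        ext5="GATC", ext3="CCGG",
        ext5_kind=Protrusion.FIVE_PRIME, ext3_kind=Protrusion.FIVE_PRIME,
        mod_ext5=Chem.HYDROXYL,   # dephosphorylated BamHI end
        mod_ext3=Chem.PHOSPHATE,  # fresh XmaI end
        name="polyA",
    )


def _chained_folder(tmp_path, label):
    """Two construction files where the second consumes the first's final
    product, plus shared oligos and GenBank plasmids."""
    donor = make_random_dna(
        400, seed=301, circular=True, name="pDonor",
        forbidden_patterns=["GAATTC", "GGATCC"],
    )
    vector = make_random_dna(
        300, seed=302, circular=True, name="pVector",
        required_sites=[("GAATTC", 50), ("GGATCC", 150)],
    )
    fwd, rev = make_primer_pair(
        donor, (100, 300), anneal_len=20,
        fwd_tail="AAGAATTC", rev_tail="AAGGATCC",
        fwd_name="fwdD", rev_name="revD",
    )
    cf_insert = "\n".join([
        "PCR\tfwdD\trevD\tpDonor\tpcrpdt",
        "Digest\tpcrpdt\tEcoRI,BamHI\t1\tinsertFrag",
    ])
    cf_assemble = "\n".join([
        "Digest\tpVector\tEcoRI,BamHI\t1\tbbFrag",
        "Ligate\tinsertFrag\tbbFrag\tpFinal",
        "Transform\tpFinal\tMach1\tAmp\tstrainFinal",
    ])
    return write_experiment_folder(
        tmp_path / label,
        # reverse-alphabetical file names: discovery order != execution order
        cfs={"z_make_insert": cf_insert, "a_assemble": cf_assemble},
        oligos={"fwdD": fwd.sequence, "revD": rev.sequence},
        plasmids={"pDonor": donor, "pVector": vector},
    )


def _parallel_folder(tmp_path, label):
    """Two independent amplifications sharing one oligo set."""
    donor = make_random_dna(400, seed=303, circular=True, name="pDonor")
    f1, r1 = make_primer_pair(donor, (0, 150), 20, fwd_name="shF", rev_name="shR1")
    _, r2 = make_primer_pair(donor, (0, 250), 20, fwd_name="shF", rev_name="shR2")
    cf1 = "PCR\tshF\tshR1\tpDonor\tampShort"
    cf2 = "PCR\tshF\tshR2\tpDonor\tampLong"
    return write_experiment_folder(
        tmp_path / label,
        cfs={"short_amp": cf1, "long_amp": cf2},
        oligos={"shF": f1.sequence, "shR1": r1.sequence, "shR2": r2.sequence},
        plasmids={"pDonor": donor},
    )


@pytest.fixture()
def chained_experiment_folder(tmp_path):
    return _chained_folder(tmp_path, "chained")


@pytest.fixture()
def parallel_experiment_folder(tmp_path):
    return _parallel_folder(tmp_path, "parallel")
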
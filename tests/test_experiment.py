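"""Construction-file execution, folder discovery, ordering, and outputs."""

import pytest

from cfsim.errors import CycleError, DigestError, MissingSequenceError, NameCollisionError
from cfsim.experiment import (
    Experiment,
    order_construction_files,
    parse_experiment_folder,
    simulate_construction_file,
    simulate_experiment,
)
from cfsim.fixtures import make_primer_pair, make_random_dna, write_experiment_folder
from cfsim.formats import parse_shorthand


@pytest.fixture()
def clone_cf_and_registry():
    """PCR -> Digest -> Digest -> Ligate: the classic four-step cloning CF."""
    donor = make_random_dna(400, seed=601, circular=True, name="pDonor",
                            forbidden_patterns=["GAATTC", "GGATCC"])
    vector = make_random_dna(300, seed=602, circular=True, name="pVector",
                             required_sites=[("GAATTC", 50), ("GGATCC", 150)])
    fwd, rev = make_primer_pair(donor, (100, 300), 20,
                                fwd_tail="AAGAATTC", rev_tail="AAGGATCC")
    text = "\n".join([
        "PCR\tfwdD\trevD\tpDonor\tpcrpdt",
        "Digest\tpcrpdt\tEcoRI,BamHI\t1\tinsertFrag",
        "Digest\tpVector\tEcoRI,BamHI\t1\tbbFrag",
        "Ligate\tinsertFrag\tbbFrag\tpFinal",
    ])
    registry = {"pDonor": donor, "pVector": vector,
                "fwdD": fwd.renamed("fwdD"), "revD": rev.renamed("revD")}
    return parse_shorthand(text, name="clone"), registry


class TestSimulateConstructionFile:
    def test_four_step_cloning_yields_circular_product(self, clone_cf_and_registry, table):
        cf, registry = clone_cf_and_registry
        products, events = simulate_construction_file(cf, registry, table)
        assert len(products) == 4 and len(events) == 4
        final = products["pFinal"]
        assert final.is_circular
        # the insert ended up inside the vector ring
        assert products["insertFrag"].sequence in final.sequence * 2

    def test_undefined_input_is_missing_sequence_error(self, table):
        cf = parse_shorthand(
            "f\tACGTACGTACGTACGTACGT\nr\tTACGTACGTACGTACGTACG\nPCR f r pTemplateX out"
        )
        with pytest.raises(MissingSequenceError, match="pTemplateX"):
            simulate_construction_file(cf, {}, table)

    def test_failure_terminates_at_step_with_context(self, clone_cf_and_registry, table):
        cf, registry = clone_cf_and_registry
        cf.steps[1].params["fragSelect"] = 9  # out of range
        with pytest.raises(DigestError, match="step 1"):
            simulate_construction_file(cf, registry, table)


class TestParseExperimentFolder:
    def test_discovers_cfs_tsv_and_genbank(self, chained_experiment_folder):
        exp = parse_experiment_folder(chained_experiment_folder)
        assert len(exp.construction_files) == 2
        assert {"fwdD", "revD", "pDonor", "pVector"} <= set(exp.sequence_registry)
        assert exp.sequence_registry["pDonor"].is_circular
        assert not exp.sequence_registry["fwdD"].is_double_stranded

    def test_empty_folder(self, tmp_path):
        exp = parse_experiment_folder(tmp_path)
        assert exp.construction_files == [] and exp.sequence_registry == {}

    def test_duplicate_name_same_sequence_deduplicated(self, tmp_path):
        oligo = "ACGTACGTACGTACGTACGT"
        folder = tmp_path / "dup"
        folder.mkdir()
        (folder / "a.tsv").write_text(f"name\tsequence\nprimer1\t{oligo}\n")
        (folder / "b.tsv").write_text(f"primer1\t{oligo}\n")
        exp = parse_experiment_folder(folder)
        assert list(exp.sequence_registry) == ["primer1"]

    def test_duplicate_name_differing_sequence_is_conflict(self, tmp_path):
        folder = tmp_path / "conflict"
        folder.mkdir()
        (folder / "a.tsv").write_text("primer1\tACGTACGTACGTACGTACGT\n")
        (folder / "b.tsv").write_text("primer1\tTTTTACGTACGTACGTACGT\n")
        with pytest.raises(NameCollisionError, match="primer1"):
            parse_experiment_folder(folder)


class TestOrdering:
    def _exp(self, texts):
        exp = Experiment()
        for name, text in texts.items():
            exp.construction_files.append(parse_shorthand(text, name=name))
        return exp

    def test_chain_supplied_in_reverse_order(self):
        exp = self._exp({
            "third": "Transform pB Mach1 strainB",
            "second": "Ligate pA extra pB",
            "first": "Ligate x y pA",
        })
        ordered = [cf.name for cf in order_construction_files(exp)]
        assert ordered == ["first", "second", "third"]

    def test_independent_files_tie_break_lexicographically(self):
        exp = self._exp({
            "one": "PCR f r t ampB",
            "two": "PCR f r t ampA",
        })
        assert [cf.final_product for cf in order_construction_files(exp)] == ["ampA", "ampB"]

    def test_cycle_detected(self):
        exp = self._exp({
            "a": "Ligate prodB x prodA",
            "b": "Ligate prodA y prodB",
        })
        with pytest.raises(CycleError):
            order_construction_files(exp)

    def test_final_product_collision(self):
        exp = self._exp({"a": "Ligate x y pSame", "b": "Ligate z w pSame"})
        with pytest.raises(NameCollisionError, match="pSame"):
            order_construction_files(exp)

    def test_intermediate_names_are_cf_local(self):
        # both files use "pcrpdt" internally; neither depends on the other
        exp = self._exp({
            "a": "PCR f r t pcrpdt\nLigate pcrpdt x outA",
            "b": "PCR f r t pcrpdt\nLigate pcrpdt y outB",
        })
        assert len(order_construction_files(exp)) == 2


class TestSimulateExperiment:
    def test_chained_run_products_and_logs(self, chained_experiment_folder, tmp_path):
        exp = parse_experiment_folder(chained_experiment_folder)
        outdir = tmp_path / "out"
        report = simulate_experiment(exp, outdir, timestamps=False)
        assert sorted(report.succeeded) == ["a_assemble", "z_make_insert"]
        assert (outdir / "insertFrag.gb").exists()
        assert (outdir / "strainFinal.gb").exists()
        assert (outdir / "C5seqs.txt").exists() and (outdir / "C5log.txt").exists()
        seqs = (outdir / "C5seqs.txt").read_text()
        for name in ("fwdD", "pDonor", "insertFrag", "strainFinal"):
            assert f"{name}\t" in seqs
        # product of the first CF shows up as a consumed input in the log
        logtext = (outdir / "C5log.txt").read_text()
        assert "insertFrag" in logtext

    def test_chained_run_is_deterministic(self, chained_experiment_folder, tmp_path):
        exp = parse_experiment_folder(chained_experiment_folder)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        simulate_experiment(exp, out1, timestamps=False)
        simulate_experiment(parse_experiment_folder(chained_experiment_folder), out2,
                            timestamps=False)
        for name in ("C5seqs.txt", "C5log.txt", "strainFinal.gb"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_genbank_products_round_trip_through_biopython(self, chained_experiment_folder, tmp_path):
        from Bio import SeqIO
        exp = parse_experiment_folder(chained_experiment_folder)
        outdir = tmp_path / "out"
        report = simulate_experiment(exp, outdir, timestamps=False)
        record = SeqIO.read(str(outdir / "strainFinal.gb"), "genbank")
        assert str(record.seq) == report.products["strainFinal"].sequence
        assert record.annotations["topology"] == "circular"

    def test_upstream_failure_skips_dependents(self, tmp_path):
        donor = make_random_dna(300, seed=603, circular=True, name="pDonor")
        folder = write_experiment_folder(
            tmp_path / "broken",
            cfs={
                # fails: primer anneals nowhere
                "make": "PCR badF badR pDonor partX",
                "use": "Ligate partX pDonor pNext",
            },
            oligos={"badF": "G" * 20, "badR": "C" * 20},
            plasmids={"pDonor": donor},
        )
        exp = parse_experiment_folder(folder)
        report = simulate_experiment(exp, tmp_path / "out", timestamps=False)
        assert "make" in report.failed
        assert report.skipped.get("use", "").startswith("skipped: upstream failure")

    def test_empty_experiment(self, tmp_path):
        report = simulate_experiment(Experiment(), tmp_path / "empty_out")
        assert report.products == {}
        assert (tmp_path / "empty_out" / "C5seqs.txt").exists()

    def test_parallel_folder_both_products(self, parallel_experiment_folder, tmp_path):
        exp = parse_experiment_folder(parallel_experiment_folder)
        report = simulate_experiment(exp, tmp_path / "out", timestamps=False)
        assert set(report.products) == {"ampShort", "ampLong"}
        assert len(report.products["ampLong"]) > len(report.products["ampShort"])
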
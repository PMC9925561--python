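import numpy as np
import pytest

from mitoplasmid.plasmids import (classify_autonomy, classify_structure,
                                  find_tirs, screen_assembly,
                                  verify_polymerases)
from mitoplasmid.seqs import MOLD_MITO, SequenceRecord, revcomp, translate
from mitoplasmid.simulate import (Degradation, GeneratorConfig,
                                  PlasmidScenario, force_orf_stops,
                                  generate_dataset, random_dna, random_protein)


def plasmid_record(dataset, contig_id):
    for h in dataset.hosts:
        for c in h.contigs:
            if c.id == contig_id:
                return c
    raise KeyError(contig_id)


class TestFindTirs:
    def test_planted_perfect_tirs_found_exactly(self):
        rng = np.random.default_rng(8)
        tir = random_dna(rng, 400)
        # 'A' collars just inside each repeat cannot self-pair, so
        # extension stops at the planted boundary
        contig = SequenceRecord(
            "p", tir + "AA" + random_dna(rng, 6000) + "AA" + revcomp(tir))
        hit = find_tirs(contig)
        assert hit is not None
        assert (hit.left_start, hit.left_end) == (0, 400)
        L = len(contig.residues)
        assert (hit.right_start, hit.right_end) == (L - 400, L)
        assert hit.length == 400 and hit.identity == 1.0

    def test_random_sequence_null_rate(self):
        """No TIR in >= 99% of seeded random 10 kb sequences."""
        rng = np.random.default_rng(0)
        fp = sum(
            find_tirs(SequenceRecord(str(i), random_dna(rng, 10000)),
                      min_len=20, min_identity=0.8) is not None
            for i in range(500))
        assert fp <= 5

    def test_palindromic_contig_spans_the_window(self):
        rng = np.random.default_rng(9)
        half = random_dna(rng, 3000)
        contig = SequenceRecord("pal", half + revcomp(half))
        hit = find_tirs(contig, window_nt=2000)
        assert hit is not None
        assert hit.length >= 1990 and hit.identity == 1.0


class TestClassifyStructure:
    def test_planted_invertron(self, default_dataset):
        contig = plasmid_record(default_dataset, "host0_plasmid0")
        call = classify_structure(contig)
        assert call.structure == "invertron"
        o1, o2 = call.orf_pair
        assert {o1.strand, o2.strand} == {"+", "-"}
        assert call.tir is not None

    def test_below_size_window_rejected(self):
        rng = np.random.default_rng(10)
        core = random_dna(rng, 300)
        orf = "".join(np.random.default_rng(1).choice(
            ["GCT", "GGT", "ATT", "TGT"], size=400))  # 1.2 kb stop-free
        seq = "TAA" + orf + "TAA" + core + revcomp("TAA" + orf + "TAA")
        assert len(seq) < 5000
        call = classify_structure(SequenceRecord("small", seq))
        assert call.structure == "none"

    def test_planted_non_invertron_with_tirs(self, default_dataset):
        contig = plasmid_record(default_dataset, "host5_plasmid0")
        call = classify_structure(contig)
        assert call.structure == "non_invertron_linear"
        o1, o2 = call.orf_pair
        assert o1.strand == o2.strand
        assert call.tir is not None

    def test_same_strand_without_tirs_is_none(self):
        rng = np.random.default_rng(11)
        orf = "".join(np.random.default_rng(2).choice(
            ["GCT", "GGT", "ATT", "TGT"], size=500))
        seq = (random_dna(rng, 1500) + "TAA" + orf + "TAA"
               + random_dna(rng, 1500) + "TAA" + orf + "TAA"
               + random_dna(rng, 1500))
        call = classify_structure(SequenceRecord("flat", seq))
        assert call.structure == "none"

    def test_invariant_under_reverse_complement(self, default_dataset):
        for cid in ["host0_plasmid0", "host5_plasmid0"]:
            contig = plasmid_record(default_dataset, cid)
            fwd = classify_structure(contig)
            rev = classify_structure(
                SequenceRecord(cid + "_rc", revcomp(contig.residues)))
            assert fwd.structure == rev.structure


class TestVerifyPolymerases:
    def test_self_panel_maximal_hit(self, default_dataset):
        contig = plasmid_record(default_dataset, "host0_plasmid0")
        call = classify_structure(contig)
        panel = [SequenceRecord(id=f"self{i}", residues=o.protein,
                                moltype="protein")
                 for i, o in enumerate(call.orf_pair)]
        call = verify_polymerases(call, panel)
        assert len(call.polymerase_evidence) == 2
        for hit, orf in zip(call.polymerase_evidence, call.orf_pair):
            assert hit.score >= 4.0 * len(orf.protein)  # ~self-identity in BLOSUM62

    def test_diverged_panel_verified(self, default_dataset):
        contig = plasmid_record(default_dataset, "host0_plasmid0")
        call = classify_structure(contig)
        call = verify_polymerases(call, default_dataset.panel, strict=True)
        assert call.structure == "invertron"
        assert all(h.score >= 100 for h in call.polymerase_evidence)

    def test_random_orfs_demoted_in_strict_mode(self):
        rng = np.random.default_rng(3)
        codons = ["GCT", "GGT", "ATT", "TGT", "CAT", "AAT"]  # stop-free
        orf1 = "".join(np.random.default_rng(4).choice(codons, size=400))
        orf2 = "".join(np.random.default_rng(5).choice(codons, size=400))
        seq = ("TAA" + orf1 + "TAA" + random_dna(rng, 2000)
               + revcomp("TAA" + orf2 + "TAA") + random_dna(rng, 2000))
        call = classify_structure(SequenceRecord("rnd", seq))
        assert call.structure == "invertron"
        panel = [SequenceRecord("pol", random_protein(rng, 800), moltype="protein")]
        call = verify_polymerases(call, panel, strict=True)
        assert call.structure == "none"

    def test_strict_without_panel_is_an_error(self, default_dataset):
        contig = plasmid_record(default_dataset, "host0_plasmid0")
        call = classify_structure(contig)
        with pytest.raises(ValueError):
            verify_polymerases(call, [], strict=True)


class TestClassifyAutonomy:
    def test_autonomous_plasmid_ends_at_tirs(self, default_dataset):
        ds = default_dataset
        contig = plasmid_record(ds, "host0_plasmid0")
        call = classify_structure(contig)
        call = classify_autonomy(call, contig, [h.mtdna for h in ds.hosts])
        assert call.autonomy == "autonomous"

    def test_inserted_plasmid_flanks_match_mtdna(self, default_dataset):
        ds = default_dataset
        contig = plasmid_record(ds, "host7_plasmid0")
        call = classify_structure(contig)
        call = classify_autonomy(call, contig, [h.mtdna for h in ds.hosts])
        assert call.autonomy == "inserted"
        assert call.flank_evidence

    def test_random_flanks_are_ambiguous(self, default_dataset):
        ds = default_dataset
        core = plasmid_record(ds, "host0_plasmid0")
        rng = np.random.default_rng(5)
        contig = SequenceRecord(
            "flanked", random_dna(rng, 500) + core.residues + random_dna(rng, 500))
        call = classify_structure(contig)
        call = classify_autonomy(call, contig, [h.mtdna for h in ds.hosts])
        assert call.autonomy == "ambiguous"

    def test_empty_mtdna_set_warns_ambiguous(self, default_dataset, caplog):
        ds = default_dataset
        core = plasmid_record(ds, "host0_plasmid0")
        rng = np.random.default_rng(6)
        contig = SequenceRecord(
            "flanked2", random_dna(rng, 500) + core.residues + random_dna(rng, 500))
        call = classify_structure(contig)
        with caplog.at_level("WARNING"):
            call = classify_autonomy(call, contig, [])
        assert call.autonomy == "ambiguous"
        assert any("no mtDNA" in r.message for r in caplog.records)


class TestScreenAssembly:
    def test_no_plants_gives_empty(self):
        cfg = GeneratorConfig(seed=21, n_hosts=1, n_decoys=30, plasmids=[],
                              tree_shape=None)
        ds = generate_dataset(cfg)
        calls, frags = screen_assembly(ds.hosts[0].contigs,
                                       mtdna_set=[ds.hosts[0].mtdna])
        assert calls == [] and frags == []

    def test_split_plasmid_rescued_as_fragments(self):
        cfg = GeneratorConfig(
            seed=22, n_hosts=1, n_decoys=20,
            plasmids=[PlasmidScenario(host=0),
                      PlasmidScenario(host=0, split=True)],
            tree_shape="(0,1);")
        ds = generate_dataset(cfg)
        known = [SequenceRecord(id="known_plasmid",
                                residues=ds.manifest["plasmids"][1]["full_sequence"])]
        calls, frags = screen_assembly(ds.hosts[0].contigs,
                                       mtdna_set=[ds.hosts[0].mtdna],
                                       known_plasmids=known)
        assert [c.contig_id for c in calls] == ["host0_plasmid0"]
        assert sorted(f.contig_id for f in frags) == [
            "host0_plasmid1_frag1", "host0_plasmid1_frag2"]

    def test_degraded_insertion_never_autonomous_invertron(self):
        """Stop-riddled polymerases cannot present as an autonomous invertron."""
        ds = generate_dataset(GeneratorConfig(
            seed=23, n_hosts=1, n_decoys=0,
            plasmids=[PlasmidScenario(host=0)], tree_shape="(0);"))
        entry = ds.manifest["plasmids"][0]
        contig = plasmid_record(ds, entry["contig_id"])
        rng = np.random.default_rng(0)
        for trial in range(10):
            seq = force_orf_stops(contig.residues,
                                  [tuple(o) for o in entry["orfs"]], 5, rng)
            call = classify_structure(SequenceRecord("degraded", seq))
            if call.structure != "none":
                call = classify_autonomy(call, SequenceRecord("degraded", seq),
                                         [ds.hosts[0].mtdna])
                assert not (call.structure == "invertron"
                            and call.autonomy == "autonomous")
            # with >= 5 stratified stops no 1 kb frame survives at all
            assert call.structure == "none"
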
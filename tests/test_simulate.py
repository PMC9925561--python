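import json

import numpy as np
import pytest

from mitoplasmid.seqs import MOLD_MITO, extract_feature, revcomp, translate
from mitoplasmid.simulate import (CaptureScenario, Degradation,
                                  GeneratorConfig, PlasmidScenario,
                                  generate_dataset, generate_mtdna,
                                  generate_trna_refs, insert_degraded_copy,
                                  write_dataset)


def contig_of(ds, cid):
    for h in ds.hosts:
        for c in h.contigs:
            if c.id == cid:
                return c
    raise KeyError(cid)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(seed=9, n_hosts=2, n_decoys=3,
                   plasmids=[PlasmidScenario(host=0)], tree_shape="(0);")
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(GeneratorConfig(**cfg)), d1)
        write_dataset(generate_dataset(GeneratorConfig(**cfg)), d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_different_seed_differs(self):
        a = generate_dataset(GeneratorConfig(seed=1, n_hosts=1, n_decoys=0,
                                             plasmids=[], tree_shape=None))
        b = generate_dataset(GeneratorConfig(seed=2, n_hosts=1, n_decoys=0,
                                             plasmids=[], tree_shape=None))
        assert a.hosts[0].mtdna.residues != b.hosts[0].mtdna.residues


class TestManifestLocatability:
    """Every planted feature must be findable at its recorded coordinates."""

    def test_tirs_orfs_and_captures(self, default_dataset):
        ds = default_dataset
        for entry in ds.manifest["plasmids"]:
            contig = contig_of(ds, entry["contig_id"])
            t = entry["tir"]
            left = contig.residues[t["left_start"]:t["left_end"]]
            right = contig.residues[t["right_start"]:t["right_end"]]
            if entry["insertion"] is None or entry["insertion"]["degradation"] is None:
                assert left == revcomp(right)
            else:
                # degraded insertions may carry substitutions in the TIRs
                matches = sum(a == b for a, b in zip(left, revcomp(right)))
                assert matches / len(left) > 0.9
            for s, e, st in entry["orfs"]:
                prot = translate(extract_feature(contig.residues, s, e, st))
                assert "*" not in prot
            cap = entry["capture"]
            if cap and cap["trna_divergence"] == 0.0:
                ref = next(t for t in ds.trna_refs if t.name == cap["trna"])
                assert contig.residues[cap["plasmid_start"]:cap["plasmid_end"]] \
                    == ref.residues

    def test_plasmid_lengths_inside_window(self, default_dataset):
        lo, hi = default_dataset.config.plasmid_size_range
        for entry in default_dataset.manifest["plasmids"]:
            assert lo <= entry["length"] <= hi

    def test_losses_removed_from_mtdna(self, default_dataset):
        ds = default_dataset
        for h, hentry in zip(ds.hosts, ds.manifest["hosts"]):
            trnas = set(h.annotations[h.annotations.feature == "tRNA"].label)
            for lost in hentry["losses"]:
                ref = next(t for t in ds.trna_refs if t.name == lost)
                assert lost not in trnas
                assert ref.residues not in h.mtdna.residues


class TestGenerateMtdna:
    def test_contains_24_trna_features_and_14_genes(self):
        cfg = GeneratorConfig(seed=4, plasmids=[], tree_shape=None)
        rng = np.random.default_rng(4)
        rec, anno, _ = generate_mtdna(cfg, rng, "h")
        assert (anno.feature == "tRNA").sum() == 24
        assert (anno.feature == "CDS").sum() == 14
        for _, r in anno.iterrows():
            sub = rec.residues[int(r.start):int(r.end)]
            assert len(sub) == int(r.end) - int(r.start)

    def test_uniform_weights_recover_uniform_family_fractions(self):
        """Per-family codon fractions stay within 3 multinomial SDs."""
        from mitoplasmid.codons import (aggregate_families, count_codons,
                                        load_family_map)
        from mitoplasmid.seqs import SequenceRecord

        fam_map = load_family_map()
        weights = {f.name: 1.0 for f in fam_map}
        cfg = GeneratorConfig(seed=6, family_weights=weights, plasmids=[],
                              tree_shape=None)
        rng = np.random.default_rng(6)
        rec, anno, _ = generate_mtdna(cfg, rng, "h")
        cds = [SequenceRecord(str(r.label),
                              rec.residues[int(r.start):int(r.end)])
               for _, r in anno[anno.feature == "CDS"].iterrows()]
        frac = aggregate_families(count_codons(cds, MOLD_MITO), fam_map)
        n = sum(cfg.gene_lengths_aa.values())  # codons incl. 14 fixed ATG starts
        n_genes = len(cfg.gene_lengths_aa)
        for f in fam_map:
            p = 1 / 24  # uniform weights are uniform per family
            if f.name == "Met-CAT":
                p = p * (n - n_genes) / n + n_genes / n
            sd = (p * (1 - p) / n) ** 0.5
            assert abs(frac[f.name] - p) < 3.5 * sd

    def test_stop_free_cds_under_mold_code(self):
        cfg = GeneratorConfig(seed=8, plasmids=[], tree_shape=None)
        rng = np.random.default_rng(8)
        rec, anno, _ = generate_mtdna(cfg, rng, "h")
        for _, r in anno[anno.feature == "CDS"].iterrows():
            prot = translate(rec.residues[int(r.start):int(r.end)], MOLD_MITO)
            assert prot[-1] == "*" and "*" not in prot[:-1]


class TestInsertDegradedCopy:
    @pytest.fixture(scope="class")
    def plasmid(self):
        ds = generate_dataset(GeneratorConfig(
            seed=30, n_hosts=1, n_decoys=0,
            plasmids=[PlasmidScenario(host=0)], tree_shape="(0);"))
        entry = ds.manifest["plasmids"][0]
        return ds, contig_of(ds, entry["contig_id"]), entry

    def test_zero_degradation_exact_substring(self, plasmid):
        ds, contig, entry = plasmid
        rng = np.random.default_rng(0)
        mut, entries = insert_degraded_copy(
            ds.hosts[0].mtdna, contig.residues,
            [tuple(o) for o in entry["orfs"]],
            Degradation(substitution_rate=0.0), rng)
        assert contig.residues in mut.residues
        e = entries[0]
        assert mut.residues[e["start"]:e["end"]] == contig.residues

    def test_fragmentation_gives_one_record_per_piece(self, plasmid):
        ds, contig, entry = plasmid
        rng = np.random.default_rng(1)
        mut, entries = insert_degraded_copy(
            ds.hosts[0].mtdna, contig.residues,
            [tuple(o) for o in entry["orfs"]],
            Degradation(substitution_rate=0.01, fragments=3), rng)
        assert len(entries) == 3
        assert sum(e["end"] - e["start"] for e in entries) == len(contig.residues)

    def test_five_stops_break_the_polymerase_frames(self, plasmid):
        from mitoplasmid.plasmids import classify_structure
        from mitoplasmid.seqs import SequenceRecord
        from mitoplasmid.simulate import force_orf_stops

        ds, contig, entry = plasmid
        rng = np.random.default_rng(2)
        for _ in range(5):
            seq = force_orf_stops(contig.residues,
                                  [tuple(o) for o in entry["orfs"]], 5, rng)
            call = classify_structure(SequenceRecord("x", seq))
            assert call.structure == "none"


class TestDatasetComposition:
    def test_default_study_conditions(self, default_dataset):
        ds = default_dataset
        m = ds.manifest
        assert m["n_hosts"] == 20
        assert len(m["plasmids"]) >= 10
        structures = [p["structure"] for p in m["plasmids"]]
        assert structures.count("non_invertron_linear") == 2
        assert sum(1 for p in m["plasmids"] if p["autonomy"] == "inserted") == 3
        assert sum(len(h["losses"]) for h in m["hosts"]) == 2
        for h in ds.hosts:
            decoys = [c for c in h.contigs if "decoy" in c.id]
            assert len(decoys) == 50

    def test_zero_hosts_empty_manifest(self):
        ds = generate_dataset(GeneratorConfig(seed=0, n_hosts=0, plasmids=[],
                                              tree_shape=None))
        assert ds.hosts == [] and ds.manifest["plasmids"] == []

    def test_manifest_is_json_serializable(self, default_dataset):
        json.dumps(default_dataset.manifest, default=int)

    def test_trna_refs_shared_across_hosts(self, default_dataset):
        ds = default_dataset
        ref = ds.trna_refs[5]
        present = sum(ref.residues in h.mtdna.residues for h in ds.hosts)
        assert present >= 18  # all hosts except any that lost this gene
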
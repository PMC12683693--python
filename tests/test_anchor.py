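import numpy as np
import pandas as pd
import pytest

from tetramap._util import DataError
from tetramap.anchor import (build_pseudomolecules, filter_alignments,
                             marey_stats, marker_physical_positions,
                             place_contigs, synteny_compare)
from tetramap.mapbuild import GeneticMap


def aln_row(marker="m1", contig="c1", start=10, end=40, strand="+",
            coverage=1.0, identity=1.0, n_hits=1):
    return dict(marker=marker, contig=contig, start=start, end=end,
                strand=strand, coverage=coverage, identity=identity,
                n_hits=n_hits)


def aln_table(rows):
    return pd.DataFrame(rows)


class TestFilterAlignments:
    def test_low_coverage_rejected(self):
        res = filter_alignments(aln_table([aln_row(coverage=0.97)]))
        assert res.retained.empty
        assert list(res.rejected["reason"]) == ["coverage"]

    def test_passing_alignment_retained(self):
        res = filter_alignments(aln_table([aln_row(coverage=1.0,
                                                   identity=0.96)]))
        assert len(res.retained) == 1
        assert res.ledger["retained"] == 1

    def test_multi_hit_rejected_when_unique_required(self):
        res = filter_alignments(aln_table([aln_row(n_hits=2)]))
        assert list(res.rejected["reason"]) == ["ambiguity"]
        res2 = filter_alignments(aln_table([aln_row(n_hits=2)]),
                                 require_unique=False)
        assert len(res2.retained) == 1
        res3 = filter_alignments(aln_table([aln_row(n_hits=5)]),
                                 require_unique=False)
        assert list(res3.rejected["reason"]) == ["ambiguity"]

    def test_contig_cap_keeps_highest_identity(self):
        rows = [aln_row(marker=f"m{i}", identity=0.95 + i * 0.0001)
                for i in range(10)]
        res = filter_alignments(aln_table(rows), max_probes_per_contig=4)
        assert len(res.retained) == 4
        assert set(res.retained["marker"]) == {"m6", "m7", "m8", "m9"}
        assert res.ledger["rejected_contig_cap"] == 6

    def test_category_order(self):
        # a probe failing several rules lands in the first category
        res = filter_alignments(aln_table([aln_row(coverage=0.5, identity=0.5,
                                                   n_hits=9)]))
        assert list(res.rejected["reason"]) == ["coverage"]


def toy_gmap():
    return GeneticMap(pd.DataFrame({
        "marker": [f"m{i}" for i in range(8)],
        "linkage_group": [1] * 6 + [2] * 2,
        "position_cM": [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 0.0, 10.0]}))


class TestPlaceContigs:
    def test_majority_vote_and_conflict_log(self):
        rows = [aln_row(marker="m0", contig="cA", start=100),
                aln_row(marker="m1", contig="cA", start=200),
                aln_row(marker="m2", contig="cA", start=300),
                aln_row(marker="m6", contig="cA", start=400),  # minority (lg 2)
                aln_row(marker="m3", contig="cB", start=10)]
        res = place_contigs(aln_table(rows), toy_gmap(),
                            {"cA": 1000, "cB": 500, "cC": 77})
        a = res.placements.set_index("contig")
        assert a.loc["cA", "chrom"] == 1
        assert (res.conflicts["reason"] == "minority_markers").any()
        assert res.unplaced == ["cC"]

    def test_tied_vote_drops_contig(self):
        rows = [aln_row(marker="m0", contig="cA", start=1),
                aln_row(marker="m6", contig="cA", start=2)]
        res = place_contigs(aln_table(rows), toy_gmap(), {"cA": 10})
        assert res.placements.empty
        assert list(res.conflicts["reason"]) == ["tied_vote"]

    def test_single_marker_contig_unoriented(self):
        rows = [aln_row(marker="m0", contig="cA", start=1)]
        res = place_contigs(aln_table(rows), toy_gmap(), {"cA": 10})
        assert res.placements["orientation"].iloc[0] == "unoriented"

    def test_orientation_sign(self):
        fwd = [aln_row(marker="m0", contig="cA", start=100),
               aln_row(marker="m1", contig="cA", start=900)]
        rev = [aln_row(marker="m0", contig="cB", start=900),
               aln_row(marker="m1", contig="cB", start=100)]
        res = place_contigs(aln_table(fwd + rev), toy_gmap(),
                            {"cA": 1000, "cB": 1000})
        a = res.placements.set_index("contig")
        assert a.loc["cA", "orientation"] == "+"
        assert a.loc["cB", "orientation"] == "-"

    def test_order_by_mean_cm(self):
        rows = [aln_row(marker="m4", contig="late", start=1),
                aln_row(marker="m0", contig="early", start=1)]
        res = place_contigs(aln_table(rows), toy_gmap(),
                            {"late": 10, "early": 10})
        ordered = res.placements.sort_values("order")["contig"]
        assert list(ordered) == ["early", "late"]

    def test_noise_free_truth_recovery(self, mixed_cross):
        from tetramap.simdata import simulate_contigs
        _, _, _, _, truth = mixed_cross
        ct = simulate_contigs(truth, np.random.default_rng(5))
        # genetic map from true marker order / positions
        names, chroms, cms = [], [], []
        for c in range(2):
            sel = truth.marker_chrom == c
            pos = truth.marker_pos[sel]
            order = np.argsort(pos)
            base = np.array([f"C{c + 1:02d}M{i + 1:04d}"
                             for i in range(sel.sum())])
            names.extend(base[order])
            chroms.extend([f"chr{c + 1}"] * sel.sum())
            cms.extend((pos[order] / pos.max() * 100.0).tolist())
        gmap = GeneticMap(pd.DataFrame({"marker": names,
                                        "linkage_group": chroms,
                                        "position_cM": cms}))
        res = place_contigs(ct.alignments, gmap, ct.contig_lengths)
        got = res.placements.set_index("contig")
        want = ct.placements.set_index("contig")
        for contig in want.index:
            if contig not in got.index:  # contigs without markers
                assert contig in res.unplaced
                continue
            assert got.loc[contig, "chrom"] == want.loc[contig, "chrom"]
            if got.loc[contig, "orientation"] != "unoriented":
                assert (got.loc[contig, "orientation"]
                        == want.loc[contig, "orientation"])
        # order within each chromosome matches the truth
        for chrom, grp in got.groupby("chrom"):
            sub = want.loc[grp.sort_values("order").index]
            assert list(sub["order"]) == sorted(sub["order"])


class TestBuildPseudomolecules:
    def placements(self, specs):
        return pd.DataFrame([{"contig": c, "chrom": ch, "order": o,
                              "orientation": ori}
                             for c, ch, o, ori in specs])

    def test_single_contig_no_gaps(self):
        p = self.placements([("c1", "chr1", 0, "+")])
        fasta, agp = build_pseudomolecules(p, {"c1": "ACGTACGT"})
        assert fasta["chr1"] == "ACGTACGT"
        assert "N" not in fasta["chr1"]
        assert len(agp) == 1

    def test_reverse_complement(self):
        p = self.placements([("c1", "chr1", 0, "-")])
        fasta, _ = build_pseudomolecules(p, {"c1": "ACGT"})
        assert fasta["chr1"] == "ACGT"  # ACGT is its own revcomp
        fasta2, _ = build_pseudomolecules(p, {"c1": "AACG"})
        assert fasta2["chr1"] == "CGTT"

    def test_gap_count_316_contigs_8_chromosomes(self):
        # 316 contigs over 8 chromosomes -> 308 junctions -> 30,800 Ns
        rng = np.random.default_rng(0)
        sizes = [40, 40, 40, 40, 40, 40, 40, 36]
        specs, seqs = [], {}
        k = 0
        for ch, n in enumerate(sizes):
            for o in range(n):
                c = f"ctg{k}"
                specs.append((c, f"chr{ch + 1}", o, "+"))
                seqs[c] = "".join(rng.choice(list("ACGT"), size=50))
                k += 1
        p = self.placements(specs)
        fasta, agp = build_pseudomolecules(p, seqs)
        assert sum(s.count("N") for s in fasta.values()) == 30_800
        assert (agp["component_type"] == "U").sum() == 308

    def test_missing_sequence_error(self):
        p = self.placements([("ghost", "chr1", 0, "+")])
        with pytest.raises(DataError, match="ghost"):
            build_pseudomolecules(p, {})

    def test_agp_fasta_mutual_consistency(self, rng):
        # reconstruct each chromosome from the AGP and compare
        specs, seqs = [], {}
        k = 0
        for ch in range(3):
            for o in range(rng.integers(1, 6)):
                c = f"c{k}"
                specs.append((c, f"chr{ch + 1}", o,
                              rng.choice(["+", "-", "unoriented"])))
                seqs[c] = "".join(rng.choice(list("ACGT"),
                                             size=rng.integers(10, 80)))
                k += 1
        p = self.placements(specs)
        fasta, agp = build_pseudomolecules(p, seqs)
        from tetramap.anchor import _revcomp
        for chrom, grp in agp.groupby("object"):
            parts = []
            for row in grp.sort_values("part_number").itertuples():
                if row.component_type == "U":
                    parts.append("N" * int(row.component_id))
                else:
                    s = seqs[row.component_id]
                    parts.append(_revcomp(s) if row.orientation == "-" else s)
                assert len(parts[-1]) == row.object_end - row.object_beg + 1
            assert "".join(parts) == fasta[chrom]
        # no loss, no duplication
        placed = set(agp.loc[agp["component_type"] == "W", "component_id"])
        assert placed == set(seqs)
        for chrom, grp in agp.groupby("object"):
            total = sum(len(seqs[r.component_id]) if r.component_type == "W"
                        else int(r.component_id)
                        for r in grp.itertuples())
            assert total == len(fasta[chrom])


class TestMareyStats:
    def marey(self, bp, cm, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "bp": bp, "cM": cm})

    def test_collinear_rho_one(self):
        bp = np.linspace(0, 1e6, 30)
        res = marey_stats(self.marey(bp, bp / 1e4))
        assert res.per_chromosome["rho"].iloc[0] == pytest.approx(1.0)

    def test_uniform_landscape_central_third(self):
        bp = np.linspace(0, 9e6, 200)
        res = marey_stats(self.marey(bp, bp / 1e5))
        assert res.per_chromosome["central_fraction"].iloc[0] == pytest.approx(
            1 / 3, abs=0.02)
        assert res.per_chromosome["class"].iloc[0] == "mixed"

    def test_pericentromeric_proximal(self):
        bp = np.linspace(0, 1e7, 300)
        x = bp / 1e7
        cm = 100 / (1 + np.exp(-12 * (x - 0.5)))  # sigmoid Marey curve
        res = marey_stats(self.marey(bp, cm))
        row = res.per_chromosome.iloc[0]
        assert row["central_fraction"] > 0.5
        assert row["class"] == "proximal"

    def test_distal_classification(self):
        bp = np.linspace(0, 1e7, 300)
        x = bp / 1e7
        # recombination at the ends, flat centre
        cm = 50 * np.clip(x / 0.2, 0, 1) + 50 * np.clip((x - 0.8) / 0.2, 0, 1)
        res = marey_stats(self.marey(bp, cm))
        row = res.per_chromosome.iloc[0]
        assert row["central_fraction"] < 0.25
        assert row["class"] == "distal"

    def test_reversal_invariance(self):
        bp = np.linspace(0, 1e7, 120)
        x = bp / 1e7
        cm = 100 / (1 + np.exp(-8 * (x - 0.4)))
        a = marey_stats(self.marey(bp, cm)).per_chromosome.iloc[0]
        b = marey_stats(self.marey(bp.max() - bp, cm[::-1])
                        ).per_chromosome.iloc[0]
        assert a["central_fraction"] == pytest.approx(
            b["central_fraction"], abs=1e-6)
        assert a["rho"] == pytest.approx(b["rho"], abs=1e-9)

    def test_degenerate_positions_error(self):
        with pytest.raises(DataError):
            marey_stats(self.marey(np.full(10, 5.0), np.arange(10.0)))

    def test_too_few_markers_skipped(self):
        with pytest.raises(DataError):
            marey_stats(self.marey([1, 2, 3], [0, 1, 2]))


class TestMarkerPhysicalPositions:
    def test_projection_through_agp(self):
        placements = pd.DataFrame([
            {"contig": "c1", "chrom": "chr1", "order": 0, "orientation": "+"},
            {"contig": "c2", "chrom": "chr1", "order": 1, "orientation": "-"}])
        seqs = {"c1": "A" * 50, "c2": "C" * 30}
        _, agp = build_pseudomolecules(placements, seqs, gap_length=10)
        aln = aln_table([aln_row(marker="mF", contig="c1", start=5),
                         aln_row(marker="mR", contig="c2", start=3)])
        pos = marker_physical_positions(agp, aln).set_index("marker")
        assert pos.loc["mF", "bp"] == 5
        # c2 begins at 61; its start=3 sits 3rd from the contig end
        assert pos.loc["mR", "bp"] == 61 + 30 - 3


class TestSyntenyCompare:
    def table(self, pos_b, chrom_b=None, chrom_a="1"):
        n = len(pos_b)
        return pd.DataFrame({
            "marker": [f"m{i}" for i in range(n)],
            "chrom_a": chrom_a, "pos_a": np.arange(n),
            "chrom_b": chrom_b if chrom_b is not None else ["1"] * n,
            "pos_b": pos_b})

    def test_identical_orders_no_inversions(self):
        rep = synteny_compare(self.table(list(range(30))))
        assert rep.inversions.empty
        assert rep.translocations.empty

    def test_middle_third_reversed(self):
        pos = list(range(30)) + list(range(59, 29, -1)) + list(range(60, 90))
        rep = synteny_compare(self.table(pos))
        assert len(rep.inversions) == 1
        inv = rep.inversions.iloc[0]
        assert inv["n_markers"] == 30
        assert inv["start_marker"] == "m30"
        assert inv["end_marker"] == "m59"

    def test_translocation_candidates(self):
        chrom_b = ["1"] * 28 + ["2", "2"]
        rep = synteny_compare(self.table(list(range(30)), chrom_b=chrom_b))
        assert len(rep.translocations) == 2
        assert set(rep.translocations["marker"]) == {"m28", "m29"}

    def test_too_few_markers_warns(self):
        with pytest.warns(UserWarning):
            rep = synteny_compare(self.table([1, 2, 3]))
        assert rep.inversions.empty
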
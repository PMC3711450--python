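"""Gene annotation, bedGraph/TSV export and domainogram matrix."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import capture3c as c3


def call_row(chrom, start, end, q, significant=True, region_id=0):
    return {
        "chrom": chrom, "start": start, "end": end, "region_id": region_id,
        "distance": 0.0, "raw_count": 10, "rpm": 5.0, "norm_rpm": 5.0,
        "signal": 5.0, "z": 3.0, "p": q / 2, "q": q,
        "significant": significant, "is_cis": True,
    }


GENES = pd.DataFrame({
    "chrom": ["chr1", "chr1"],
    "start": [100_000, 300_000],
    "end": [105_000, 310_000],
    "strand": ["+", "-"],
    "name": ["geneA", "geneB"],
})


class TestAnnotateGenes:
    def test_upstream_window_overlap_reported(self):
        calls = pd.DataFrame([call_row("chr1", 60_000, 64_000, 0.01)])
        hits = c3.annotate_genes(calls, GENES)
        assert hits["gene"].tolist() == ["geneA"]

    def test_call_beyond_window_not_reported(self):
        calls = pd.DataFrame([call_row("chr1", 40_000, 44_000, 0.01)])
        hits = c3.annotate_genes(calls, GENES)
        assert "geneA" not in hits["gene"].tolist()

    def test_zero_windows_require_body_overlap(self):
        cfg = c3.AnnotationConfig(upstream_bp=0, downstream_bp=0)
        inside = pd.DataFrame([call_row("chr1", 101_000, 102_000, 0.01)])
        outside = pd.DataFrame([call_row("chr1", 99_000, 99_900, 0.01)])
        assert c3.annotate_genes(inside, GENES, cfg)["gene"].tolist() == ["geneA"]
        assert c3.annotate_genes(outside, GENES, cfg).empty

    def test_minus_strand_window_mirrored(self):
        # geneB is minus strand: upstream extends beyond the gene end
        up = pd.DataFrame([call_row("chr1", 350_000, 352_000, 0.01)])
        down = pd.DataFrame([call_row("chr1", 250_000, 252_000, 0.01)])
        assert c3.annotate_genes(up, GENES)["gene"].tolist() == ["geneB"]
        assert c3.annotate_genes(down, GENES).empty

    def test_best_call_is_minimum_q(self):
        calls = pd.DataFrame([
            call_row("chr1", 101_000, 102_000, 0.04, region_id=1),
            call_row("chr1", 103_000, 104_000, 0.001, region_id=2),
        ])
        hits = c3.annotate_genes(calls, GENES)
        row = hits.set_index("gene").loc["geneA"]
        assert row["best_region_id"] == 2
        assert row["n_calls"] == 2

    def test_enlarging_windows_never_removes_genes(self):
        rng = np.random.default_rng(6)
        calls = pd.DataFrame([
            call_row("chr1", int(s), int(s) + 2000, 0.01, region_id=i)
            for i, s in enumerate(rng.integers(0, 500_000, 20))
        ])
        small = c3.annotate_genes(
            calls, GENES, c3.AnnotationConfig(10_000, 1_000)
        )
        large = c3.annotate_genes(
            calls, GENES, c3.AnnotationConfig(80_000, 20_000)
        )
        assert set(small["gene"]) <= set(large["gene"])

    def test_insignificant_calls_ignored(self):
        calls = pd.DataFrame([
            call_row("chr1", 101_000, 102_000, 0.5, significant=False)
        ])
        assert c3.annotate_genes(calls, GENES).empty


class TestGeneModelIO:
    def test_gtf_gene_features(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "g1"; gene_name "Alpha";\n'
            'chr1\tx\texon\t101\t150\t.\t+\t.\tgene_id "g1"; gene_name "Alpha";\n'
            'chr2\tx\tgene\t501\t900\t.\t-\t.\tgene_id "g2";\n'
        )
        genes = c3.read_gene_models(gtf)
        assert genes["name"].tolist() == ["Alpha", "g2"]
        assert genes["start"].tolist() == [100, 500]  # 1-based -> 0-based
        assert genes["end"].tolist() == [200, 900]

    def test_bed6(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tAlpha\t0\t+\nchr2\t500\t900\tBeta\t0\t-\n")
        genes = c3.read_gene_models(bed)
        assert genes["name"].tolist() == ["Alpha", "Beta"]
        assert genes["strand"].tolist() == ["+", "-"]


class TestBedGraph:
    def test_format_line(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["chrT"], "start": [3], "end": [13], "norm_rpm": [250.0],
        })
        path = c3.export_bedgraph(df, "norm_rpm", tmp_path / "t.bedGraph",
                                  track_name="sig")
        lines = path.read_text().splitlines()
        assert lines[0] == "track type=bedGraph name=sig"
        assert lines[1] == "chrT\t3\t13\t250"

    def test_zero_values_omitted_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(50) * 100,
            "end": (np.arange(50) + 1) * 100,
            "value": np.round(rng.random(50) * np.array([0, 1] * 25), 4),
        })
        path = c3.export_bedgraph(df, "value", tmp_path / "v.bedGraph")
        back = c3.read_bedgraph(path)
        nz = df[df["value"] > 0].reset_index(drop=True)
        assert len(back) == len(nz)
        assert np.allclose(back["value"], nz["value"], rtol=1e-5)
        assert back[["start", "end"]].equals(nz[["start", "end"]])

    def test_empty_input_gives_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        path = c3.export_bedgraph(df, "value", tmp_path / "e.bedGraph")
        assert path.read_text() == "track type=bedGraph name=capture3c\n"

    def test_overlapping_regions_rejected(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 50], "end": [100, 150],
            "value": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="overlap"):
            c3.export_bedgraph(df, "value", tmp_path / "o.bedGraph")


class TestTextExport:
    def test_row_count_and_round_trip(self, tmp_path):
        calls = pd.DataFrame([
            call_row("chr1", 1000, 2000, 0.0123456789, region_id=1),
            call_row("chr1", 3000, 4000, 0.5, significant=False, region_id=2),
            call_row("chr2", 1000, 2000, 1e-12, region_id=3),
        ])
        path = c3.export_text(calls, tmp_path / "calls.tsv")
        text = path.read_text().splitlines()
        assert len(text) == 4  # header + 3 rows
        back = c3.read_calls(path)
        assert np.allclose(back["q"], calls["q"], rtol=1e-5)
        assert back["significant"].tolist() == calls["significant"].tolist()
        assert back["region_id"].tolist() == [1, 2, 3]

    def test_empty_input_gives_header_only(self, tmp_path):
        calls = pd.DataFrame(columns=["chrom", "start", "end", "q"])
        path = c3.export_text(calls, tmp_path / "empty.tsv")
        assert len(path.read_text().splitlines()) == 1

    def test_bedgraph_and_tsv_agree(self, tmp_path):
        calls = pd.DataFrame([
            call_row("chr1", 1000, 2000, 0.01, region_id=1),
            call_row("chr1", 5000, 6000, 0.02, region_id=2),
        ])
        bg = c3.read_bedgraph(
            c3.export_bedgraph(calls, "signal", tmp_path / "a.bedGraph")
        )
        tsv = c3.read_calls(c3.export_text(calls, tmp_path / "a.tsv"))
        assert np.allclose(bg["value"].to_numpy(), tsv["signal"].to_numpy())
        assert bg["start"].tolist() == tsv["start"].tolist()


@pytest.fixture(scope="module")
def spiked_block_matrix(default_sim):
    """Spike a ~10-kb block of adjacent fragments near the viewpoint."""
    cfg, fm, vp = default_sim
    sub = fm.fragments_on(vp.chrom)
    mid = (sub["start"] + sub["end"]) / 2
    d = mid - vp.midpoint
    block = sub[(d > 200_000) & (d < 215_000)]
    spikes = tuple((int(i), 10.0) for i in block["fragment_id"])
    reads, _ = c3.simulate_3cseq(
        dataclasses.replace(cfg, seed=77, spikes=spikes), fm
    )
    mat = c3.domainogram_matrix(reads, vp, fm.chrom_sizes, span_bp=400_000)
    center = int(block["start"].iloc[0] + 5000)
    return mat, center


class TestDomainogram:
    def test_has_29_rows_for_default_sizes(self, spiked_block_matrix):
        mat, _ = spiked_block_matrix
        assert mat.q.shape[0] == 29
        assert mat.q.index.tolist() == list(range(2000, 31000, 1000))

    def test_spiked_block_persists_across_sizes(self, spiked_block_matrix):
        mat, center = spiked_block_matrix
        cols = mat.q.columns.to_numpy()
        j = int(np.argmin(np.abs(cols - center)))
        qcol = mat.q.iloc[:, j].to_numpy()
        assert np.nansum(qcol <= 0.05) >= 15  # low q across most sizes

    def test_null_has_no_persistent_column(self, default_sim):
        cfg, fm, vp = default_sim
        reads, _ = c3.simulate_3cseq(dataclasses.replace(cfg, seed=78), fm)
        mat = c3.domainogram_matrix(reads, vp, fm.chrom_sizes,
                                    span_bp=400_000)
        persistent = np.nansum(mat.q.to_numpy() <= 0.01, axis=0)
        assert (persistent >= 25).sum() == 0

    def test_transformed_is_capped_neg_log10(self, spiked_block_matrix):
        mat, _ = spiked_block_matrix
        t = mat.transformed(cap=10.0)
        assert t.to_numpy().max() <= 10.0
        assert t.to_numpy().min() >= 0.0

    def test_span_smaller_than_window_rejected(self, default_sim):
        cfg, fm, vp = default_sim
        reads = pd.DataFrame(columns=["chrom", "start", "end", "strand",
                                      "mapq", "five_prime"])
        with pytest.raises(ValueError, match="span"):
            c3.domainogram_matrix(reads, vp, fm.chrom_sizes, span_bp=10_000)
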
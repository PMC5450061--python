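"""Informative germline site selection, allele-pattern calling, somatic tallies."""

import numpy as np
import pandas as pd
import pytest

from cellverdict import snv
from cellverdict.cnv import CnvSegment


def make_sites(rows):
    return pd.DataFrame(
        rows,
        columns=["site_id", "chrom", "pos", "ref", "alt", "kind", "vaf_blood", "vaf_tumor"],
    )


SEGMENTS = [
    CnvSegment("chr10", 0, 50_000_000, "loss", 0.55),
    CnvSegment("chr7", 0, 1, "gain", 1.45, whole_chromosome=True),
]


class TestInformativeGermline:
    def test_unshifted_site_excluded(self):
        sites = make_sites([("s1", "chr10", 100, "A", "G", "germline", 0.5, 0.5)])
        assert snv.select_informative_germline(sites, SEGMENTS).empty

    def test_predicate_matches_brute_force_on_hand_made_sites(self):
        rows = [
            ("a", "chr10", 100, "A", "G", "germline", 0.50, 0.10),   # keep (loss)
            ("b", "chr10", 200, "A", "G", "germline", 0.70, 0.10),   # not het in blood
            ("c", "chr10", 300, "A", "G", "germline", 0.50, 0.40),   # shift too small
            ("d", "chr1", 400, "A", "G", "germline", 0.50, 0.05),    # outside segments
            ("e", "chr7", 500, "A", "G", "germline", 0.45, 0.90),    # keep (gain)
            ("f", "chr10", 600, "A", "G", "somatic", 0.50, 0.10),    # wrong kind
        ]
        sites = make_sites(rows)
        got = snv.select_informative_germline(sites, SEGMENTS, het_tol=0.1, shift_min=0.15)
        # brute-force predicate, written independently
        expected = set()
        for sid, chrom, pos, _, _, kind, vb, vt in rows:
            if kind != "germline" or abs(vb - 0.5) > 0.1 or abs(vt - 0.5) < 0.15:
                continue
            for seg in SEGMENTS:
                if chrom == seg.chrom and (seg.whole_chromosome or seg.start <= pos <= seg.end):
                    expected.add(sid)
        assert set(got["site_id"]) == expected == {"a", "e"}
        assert got.set_index("site_id").loc["e", "segment_direction"] == "gain"

    def test_no_segments_yields_empty_with_warning(self, caplog):
        sites = make_sites([("s1", "chr10", 100, "A", "G", "germline", 0.5, 0.1)])
        with caplog.at_level("WARNING"):
            out = snv.select_informative_germline(sites, [])
        assert out.empty and "no CNV segments" in caplog.text

    def test_invariant_to_input_ordering(self):
        rows = [
            ("a", "chr10", 100, "A", "G", "germline", 0.50, 0.10),
            ("e", "chr7", 500, "A", "G", "germline", 0.45, 0.90),
        ]
        fwd = snv.select_informative_germline(make_sites(rows), SEGMENTS)
        rev = snv.select_informative_germline(make_sites(rows[::-1]), SEGMENTS)
        pd.testing.assert_frame_equal(fwd, rev)


def make_counts(rows):
    df = pd.DataFrame(
        rows, columns=["cell_id", "site_id", "ref_count", "alt_count"]
    )
    return df


INFORMATIVE = pd.DataFrame(
    {
        "site_id": ["L1", "L2", "G1"],
        "segment_id": ["chr10:loss", "chr10:loss", "chr7:gain"],
        "segment_direction": ["loss", "loss", "gain"],
    }
)


class TestAllelePattern:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (0, 0, snv.NO_COVERAGE),
            (2, 0, snv.NO_COVERAGE),  # below min_reads=3
            (5, 0, snv.REF_ONLY),
            (0, 5, snv.ALT_ONLY),
            (3, 4, snv.BIALLELIC),
            (4, 1, snv.REF_ONLY),  # minor allele below min_minor=2
        ],
    )
    def test_site_call_rules(self, ref, alt, expected):
        calls, _ = snv.call_allele_pattern(
            make_counts([("c1", "L1", ref, alt)]), INFORMATIVE,
            min_reads=3, min_minor=2,
        )
        assert calls.loc[0, "call"] == expected

    def test_cell_summaries(self):
        counts = make_counts(
            [
                ("mono", "L1", 6, 0), ("mono", "L2", 0, 4),
                ("bi", "L1", 3, 3), ("bi", "L2", 5, 0),
                ("nocov", "L1", 1, 0),
            ]
        )
        _, summary = snv.call_allele_pattern(
            counts, INFORMATIVE, cells=["mono", "bi", "nocov", "missing"]
        )
        got = summary.set_index("cell_id")["summary"]
        assert got["mono"] == snv.MONOALLELIC_CONSISTENT
        assert got["bi"] == snv.BIALLELIC_OBSERVED
        assert got["nocov"] == snv.UNINFORMATIVE
        assert got["missing"] == snv.UNINFORMATIVE
        assert summary.set_index("cell_id").loc["bi", "n_biallelic_loss"] == 1

    def test_unknown_sites_rejected_with_offenders(self):
        counts = make_counts([("c1", "MYSTERY", 3, 3)])
        with pytest.raises(ValueError, match="MYSTERY"):
            snv.call_allele_pattern(
                counts, INFORMATIVE, known_sites=["L1", "L2", "G1", "S1"]
            )

    def test_other_known_site_classes_ignored(self):
        counts = make_counts([("c1", "S1", 3, 3), ("c1", "L1", 5, 0)])
        calls, summary = snv.call_allele_pattern(
            counts, INFORMATIVE, known_sites=["S1"]
        )
        assert set(calls["site_id"]) == {"L1"}
        assert summary.loc[0, "summary"] == snv.MONOALLELIC_CONSISTENT


SOMATIC_SITES = pd.DataFrame({"site_id": [f"S{i}" for i in range(4)]})


class TestSomaticTally:
    def test_all_zero_alt_counts_give_zero_tally(self):
        counts = make_counts([("c1", "S0", 5, 0), ("c1", "S1", 2, 0)])
        tally = snv.tally_somatic(counts, SOMATIC_SITES)
        assert tally["n_somatic_expressed"].tolist() == [0]

    def test_toy_table_matches_exhaustive_count(self):
        rng = np.random.default_rng(5)
        rows = [
            (cell, f"S{i}", int(rng.integers(0, 5)), int(rng.integers(0, 3)))
            for cell in ["c1", "c2", "c3"]
            for i in range(4)
        ]
        tally = snv.tally_somatic(make_counts(rows), SOMATIC_SITES, min_alt=1)
        expected = {
            cell: sum(1 for r in rows if r[0] == cell and r[3] >= 1)
            for cell in ["c1", "c2", "c3"]
        }
        assert dict(zip(tally["cell_id"], tally["n_somatic_expressed"])) == expected

    def test_monotone_in_min_alt(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"c{j}", f"S{i}", 0, int(rng.integers(0, 6)))
            for j in range(5)
            for i in range(4)
        ]
        counts = make_counts(rows)
        prev = None
        for min_alt in [1, 2, 3, 4]:
            tally = snv.tally_somatic(counts, SOMATIC_SITES, min_alt=min_alt)
            vals = tally.set_index("cell_id")["n_somatic_expressed"]
            if prev is not None:
                assert (vals <= prev.reindex(vals.index).fillna(0)).all()
            prev = vals

    def test_invariant_n_equals_sites_detected(self):
        rows = [("c1", "S0", 0, 2), ("c1", "S2", 1, 1), ("c1", "S3", 3, 0)]
        tally = snv.tally_somatic(make_counts(rows), SOMATIC_SITES)
        row = tally.iloc[0]
        listed = [s for s in row["sites_detected"].split(";") if s]
        assert row["n_somatic_expressed"] == len(listed) == 2
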
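"""Summary fixture arithmetic, audit, and the timing regression."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from satkit.reporting import (
    ReplicationRecord,
    SatelliteRecord,
    audit_mbp,
    fixture_counts,
    mbp_per_1c,
    read_fixture,
    read_summary,
    replication_regression,
    write_summary,
)


class TestMbpPer1C:
    @pytest.mark.parametrize(
        "pct,expected", [(2.322, 311.4), (0.222, 29.8), (0.008, 1.1), (0.0, 0.0)]
    )
    def test_printed_conversions(self, pct, expected):
        assert mbp_per_1c(pct, 13410) == expected

    def test_half_rounds_away_from_zero(self):
        assert mbp_per_1c(0.25, 100) == 0.3  # 0.25 Mbp -> 0.3, not banker's 0.2

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mbp_per_1c(-1.0, 13410)


@pytest.fixture(scope="module")
def fix():
    return read_fixture()


class TestFixture:

    def test_shape(self, fix):
        assert len(fix) == 26
        assert fixture_counts(fix, "name", "startswith", "VfSat") == 23
        assert fixture_counts(fix, "pct_genome", "ge", 0) == 26  # always-true

    def test_headline_counts(self, fix):
        assert fixture_counts(fix, "pct_genome", "gt", 0.1) == 10
        assert fixture_counts(fix, "monomer_bp", "between", (687, 2033)) == 17
        assert fixture_counts(fix, "chip_input_ratio", "gt", 10) == 7

    def test_centromere_label_implies_enrichment_call(self, fix):
        for r in fix:
            if r.centromere:
                assert r.chip_input_ratio > 10

    def test_special_rows_transcribed_losslessly(self, fix):
        by_name = {r.name: r for r in fix}
        assert by_name["VfSat2"].monomer_approx and by_name["VfSat2"].monomer_bp == 26
        assert by_name["FokI"].monomer_bp == 59 and by_name["FokI"].monomer_bp_variant == 57

    def test_unknown_field_rejected(self, fix):
        with pytest.raises(ValueError):
            fixture_counts(fix, "no_such_column", "gt", 1)

    def test_audit_reports_known_discrepancies(self, fix):
        audit = audit_mbp(fix)
        flagged = set(audit["satellite"])
        assert {"VfSat1", "VfSat6"} <= flagged
        # reported, never corrected: the stored record keeps the printed value
        by_name = {r.name: r for r in fix}
        assert by_name["VfSat6"].mbp_1c == 17.6

    def test_roundtrip(self, fix, tmp_path):
        path = tmp_path / "summary.tsv"
        write_summary(fix, str(path))
        again = read_summary(str(path))
        assert again == fix
        header = path.read_text().splitlines()[0]
        assert header.startswith("satellite\tmonomer_bp")

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        good = read_fixture()
        write_summary(good[:2], str(path))
        text = path.read_text().replace("191", "not-a-number")
        path.write_text(text)
        with pytest.raises(ValueError, match="line 2"):
            read_summary(str(path))


def synthetic_families(rng, n=26):
    at = np.linspace(55, 80, n) + rng.normal(0, 1, n)
    monomer = rng.integers(26, 2033, n)
    return pd.DataFrame({"pct_at": at, "monomer_bp": monomer},
                        index=[f"fam{i}" for i in range(n)])


def classes_from_order(values, index):
    order = np.argsort(values)
    classes = np.empty(len(values), dtype=object)
    classes[order[: len(values) // 3]] = "mid"
    classes[order[len(values) // 3 : 2 * len(values) // 3]] = "late"
    classes[order[2 * len(values) // 3 :]] = "latest"
    return [ReplicationRecord(f, c) for f, c in zip(index, classes)]


class TestReplicationRegression:
    def test_planted_signal_detected(self, rng):
        feats = synthetic_families(rng)
        classes = classes_from_order(feats["pct_at"].to_numpy(), feats.index)
        out = replication_regression(feats, classes).set_index("feature")
        assert out.loc["pct_at", "p"] < 0.05
        assert out.loc["pct_at", "slope"] > 0

    def test_constant_feature_gives_nan_with_warning(self, rng):
        feats = synthetic_families(rng)
        feats["flat"] = 1.0
        classes = classes_from_order(feats["pct_at"].to_numpy(), feats.index)
        with pytest.warns(UserWarning, match="constant"):
            out = replication_regression(feats, classes).set_index("feature")
        assert np.isnan(out.loc["flat", "p"])

    def test_invalid_timing_class_rejected(self):
        with pytest.raises(ValueError):
            ReplicationRecord("f", "early")

    def test_bh_adjustment_column(self, rng):
        feats = synthetic_families(rng)
        classes = classes_from_order(feats["pct_at"].to_numpy(), feats.index)
        out = replication_regression(feats, classes, adjust=True)
        assert "q" in out.columns and (out["q"] >= out["p"]).all()

    def test_null_pvalues_approximately_uniform(self, rng):
        """Pure-noise features should give uniform p-values."""
        pvals = []
        for _ in range(300):
            feats = pd.DataFrame(
                {"noise": rng.normal(size=26)}, index=[f"f{i}" for i in range(26)]
            )
            timing = rng.permutation(
                ["mid"] * 9 + ["late"] * 9 + ["latest"] * 8
            )
            classes = [ReplicationRecord(f, c) for f, c in zip(feats.index, timing)]
            pvals.append(replication_regression(feats, classes)["p"].iloc[0])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 1e-3
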
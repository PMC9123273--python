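from datetime import date

import pytest

from strokekit.cohort_accounting import (CohortManifest, ManifestRow,
                                         chronological_split, read_manifest,
                                         round_half_up, summarize,
                                         write_manifest, write_summary)


def _rows(n, start=date(2020, 1, 1), **kw):
    from datetime import timedelta

    return [ManifestRow(f"p{i:03d}", start + timedelta(days=i), **kw)
            for i in range(n)]


class TestManifest:
    def test_duplicate_ids_rejected(self):
        rows = [ManifestRow("x", date(2020, 1, 1)),
                ManifestRow("x", date(2020, 1, 2))]
        with pytest.raises(ValueError, match="duplicate"):
            CohortManifest(rows)

    def test_excluded_needs_reason(self):
        with pytest.raises(ValueError, match="reason"):
            ManifestRow("x", date(2020, 1, 1), excluded=True)


class TestChronologicalSplit:
    def test_ten_patients_eight_two(self):
        dev, test = chronological_split(CohortManifest(_rows(10)))
        assert len(dev) == 8 and len(test) == 2
        assert test == ["p008", "p009"]

    def test_216_boundary_ceil(self):
        dev, test = chronological_split(CohortManifest(_rows(216)))
        assert (len(dev), len(test)) == (173, 43)

    def test_excluded_not_split(self):
        rows = _rows(9) + [ManifestRow("pz", date(2021, 1, 1), excluded=True,
                                       exclusion_reason="DWI-negative")]
        dev, test = chronological_split(CohortManifest(rows))
        assert "pz" not in dev + test

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            chronological_split(CohortManifest(_rows(4)), dev_fraction=1.0)

    def test_deterministic_tie_break(self):
        rows = [ManifestRow(pid, date(2020, 1, 1)) for pid in "dcba"]
        dev, test = chronological_split(CohortManifest(rows),
                                        dev_fraction=0.5)
        assert dev == ["a", "b"] and test == ["c", "d"]


class TestSummarize:
    def test_printed_ratios(self):
        rows = ([ManifestRow(f"a{i}", date(2020, 1, 1),
                             territory_label="anterior") for i in range(111)]
                + [ManifestRow(f"p{i}", date(2020, 1, 1),
                               territory_label="posterior")
                   for i in range(51)])
        s = summarize(CohortManifest(rows))
        t = {r["label"]: r["percent"] for r in s["territory"]}
        assert t == {"anterior": 68.5, "posterior": 31.5}

    def test_exclusion_percentages(self):
        rows = (_rows(228, size_label="lacune")
                + [ManifestRow(f"e{i}", date(2021, 1, 1), excluded=True,
                               exclusion_reason="DWI-negative")
                   for i in range(11)])
        s = summarize(CohortManifest(rows))
        assert s["screened"] == 239
        assert s["excluded"]["percent_of_screened"] == 4.6
        assert s["excluded"]["by_reason"] == {"DWI-negative": 11}

    def test_percentages_sum_to_100(self):
        rows = (_rows(7, size_label="lacune")
                + [ManifestRow(f"n{i}", date(2021, 1, 1),
                               size_label="non_lacune") for i in range(6)])
        s = summarize(CohortManifest(rows))
        total = sum(r["percent"] for r in s["size"])
        assert abs(total - 100.0) <= 0.1

    def test_empty_manifest(self):
        s = summarize(CohortManifest([]))
        assert s["screened"] == 0
        assert s["size"] == [] and s["territory"] == []

    def test_split_sections(self):
        m = CohortManifest(_rows(10, size_label="lacune"))
        dev, test = chronological_split(m)
        s = summarize(m, (dev, test))
        assert s["development"]["count"] == 8
        assert s["test"]["count"] == 2


class TestRounding:
    def test_half_up(self):
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(2.35, 1) == 2.4  # not banker's rounding
        assert round_half_up(100 * 11 / 216) == 5.1


class TestIO:
    def test_round_trip(self, tmp_path):
        m = CohortManifest(_rows(4, size_label="lacune",
                                 territory_label="anterior"))
        path = tmp_path / "m.tsv"
        write_manifest(m, path)
        back = read_manifest(path)
        assert back.rows == m.rows

    def test_unparseable_date(self, tmp_path):
        m = CohortManifest(_rows(2))
        path = tmp_path / "m.tsv"
        write_manifest(m, path)
        path.write_text(path.read_text().replace("2020-01-01", "not-a-date"))
        with pytest.raises(ValueError, match="unparseable"):
            read_manifest(path)

    def test_summary_files(self, tmp_path):
        m = CohortManifest(_rows(4, size_label="lacune"))
        write_summary(summarize(m), tmp_path / "s.tsv", tmp_path / "s.json")
        assert (tmp_path / "s.tsv").read_text().startswith("section")
        import json
        data = json.loads((tmp_path / "s.json").read_text())
        assert data["screened"] == 4
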
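import math

import pytest

from pufalakes.data_model import (
    CommunityResponses,
    SurveySample,
    TableFormatError,
    TaxonPufaProfile,
    read_responses,
    read_survey,
    read_taxon_table,
    write_responses,
    write_survey,
    write_taxon_table,
)
from pufalakes.community_metrics import responses_for_survey
from pufalakes.synthetic_data import GeneratorConfig, generate_survey

from conftest import make_sample


class TestTaxonTable:
    def test_reference_table_content(self, reference_profiles, profile_table):
        assert len(reference_profiles) == 24
        assert sum(p.n_lakes for p in reference_profiles) == 238
        pallasidae = profile_table["Amphipoda/Pallasidae"]
        assert pallasidae.mean_dha == pytest.approx(4.6)
        assert pallasidae.class_dha == 5
        isopoda = profile_table["Isopoda (Asellus aquaticus)"]
        assert (isopoda.mean_ara, isopoda.class_ara) == (4.0, 5)
        assert (isopoda.mean_epa, isopoda.class_epa) == (5.0, 2)

    def test_missing_sd_kept_missing(self, profile_table):
        nematoda = profile_table["Nematoda"]
        assert nematoda.sd_ara is None and nematoda.sd_dha is None
        assert nematoda.mean_dha == 0.0 and nematoda.class_dha == 1

    def test_round_trip(self, reference_profiles, tmp_path):
        path = tmp_path / "taxa.csv"
        write_taxon_table(reference_profiles, path)
        assert read_taxon_table(path) == reference_profiles

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(TableFormatError, match="no records"):
            read_taxon_table(path)
        header_only = tmp_path / "header.csv"
        header_only.write_text(
            "taxon,n_lakes,mean_ara,sd_ara,class_ara,mean_epa,sd_epa,class_epa,"
            "mean_dha,sd_dha,class_dha\n"
        )
        with pytest.raises(TableFormatError, match="no records"):
            read_taxon_table(header_only)

    def test_negative_mass_fraction_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "taxon,n_lakes,mean_ara,sd_ara,class_ara,mean_epa,sd_epa,class_epa,"
            "mean_dha,sd_dha,class_dha\n"
            "X,3,-1.0,0.5,2,1.0,0.5,3,0.1,0.1,3\n"
        )
        with pytest.raises(TableFormatError, match="line 2"):
            read_taxon_table(path)

    def test_class1_must_match_zero_mean(self):
        with pytest.raises(ValueError, match="class 1"):
            TaxonPufaProfile(
                taxon="X", n_lakes=2,
                mean_ara=1.0, sd_ara=0.1, class_ara=1,  # nonzero mean, class 1
                mean_epa=1.0, sd_epa=0.1, class_epa=3,
                mean_dha=0.0, sd_dha=None, class_dha=1,
            )


class TestSurveyTable:
    def test_validation_rejects_nonpositive_covariates(self):
        with pytest.raises(ValueError, match="ph"):
            make_sample({"A": 1}, ph=0.0)
        with pytest.raises(ValueError, match="color"):
            make_sample({"A": 1}, color=-3.0)

    def test_requires_a_present_taxon(self):
        with pytest.raises(ValueError, match="at least one taxon"):
            make_sample({"A": 0, "B": 0})

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip(self, tmp_path, layout):
        samples = generate_survey(GeneratorConfig(n_lakes=8, seed=1))
        path = tmp_path / "survey.csv"
        write_survey(samples, path, layout=layout)
        assert read_survey(path, layout=layout) == samples

    def test_full_scale_survey_has_95_lakes(self, tmp_path):
        samples = generate_survey(GeneratorConfig(seed=1))
        assert len({s.lake_id for s in samples}) == 95
        path = tmp_path / "survey.csv"
        write_survey(samples, path)
        assert read_survey(path) == samples

    def test_ph_zero_in_file_rejected(self, tmp_path):
        samples = generate_survey(GeneratorConfig(n_lakes=3, seed=2))
        path = tmp_path / "survey.csv"
        write_survey(samples, path)
        text = path.read_text().splitlines()
        header = text[0].split(",")
        row = text[1].split(",")
        row[header.index("ph")] = "0"
        path.write_text("\n".join([text[0], ",".join(row)] + text[2:]))
        with pytest.raises(TableFormatError, match="line 2"):
            read_survey(path)


class TestResponsesTable:
    def test_row_count_and_round_trip(self, tmp_path, reference_profiles):
        samples = generate_survey(GeneratorConfig(n_lakes=3, seed=3))[:3]
        records = responses_for_survey(samples, reference_profiles)
        path = tmp_path / "responses.csv"
        write_responses(records, path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        assert len(lines) == 1 + 3  # header + one row per site
        assert read_responses(path) == records

    def test_empty_record_list_gives_header_only(self, tmp_path):
        path = tmp_path / "responses.csv"
        write_responses([], path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        assert len(lines) == 1

    def test_count_ordering_enforced(self):
        with pytest.raises(ValueError, match="count_gt4"):
            CommunityResponses(
                lake_id="L", site_id="S", richness=4,
                abundance_fa_weighted={"ara": 1.0, "epa": 1.0, "dha": 1.0},
                fa_abundance_weighted={"ara": 1.0, "epa": 1.0, "dha": 1.0},
                fa_x_abundance={"ara": 1.0, "epa": 1.0, "dha": 1.0},
                count_gt3={"ara": 1, "epa": 1, "dha": 1},
                count_gt4={"ara": 2, "epa": 1, "dha": 1},  # > count_gt3
                pct_gt3={"ara": 0.25, "epa": 0.25, "dha": 0.25},
                pct_gt4={"ara": 0.5, "epa": 0.25, "dha": 0.25},
            )
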
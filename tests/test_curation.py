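import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ureascape import curation
from ureascape.curation import (
    RawActivityRecord,
    StructureError,
    classify_activity,
    curate,
    deduplicate,
    exclude_structure,
    impute_qualitative_inactive,
    normalize_activity,
    normalize_records,
    read_raw_csv,
    standardize_structure,
)

from conftest import make_record


class TestStandardize:
    def test_deterministic(self):
        assert standardize_structure("CCO") == standardize_structure("CCO")

    def test_aromatic_perception(self):
        # kekulized and aromatic benzene denote one molecule
        _, key1 = standardize_structure("C1=CC=CC=C1")
        _, key2 = standardize_structure("c1ccccc1")
        assert key1 == key2

    def test_salt_stripping(self):
        _, salt = standardize_structure("CC(=O)[O-].[Na+]")
        _, acid = standardize_structure("CC(=O)O")
        assert salt == acid

    def test_roundtrip(self):
        smiles, key = standardize_structure("Oc1ccc(Cl)cc1")
        assert standardize_structure(smiles)[1] == key

    def test_parse_error_carries_record_id(self):
        with pytest.raises(StructureError) as err:
            standardize_structure("not_a_smiles", record_id="r42")
        assert err.value.record_id == "r42"


class TestExclude:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCO", None),
            ("c1ccc(C(=O)O)cc1", None),
            ("CC(=O)[O-].[Na+]", None),  # counterion stripped, parent kept
            ("[Ni]([NH3])([NH3])Cl", "metal_complex"),
            ("N[Pt](N)(Cl)Cl", "metal_complex"),
            ("C1=CC(=O)C=CC1=O.[Cu]", "metal_complex"),
            ("CCO.CCC", None),  # ethanol is a known solvent, stripped
            ("NC(=O)c1ccccc1.OC(=O)c1ccncc1", "mixture"),
            ("xyz(", "parse_error"),
        ],
    )
    def test_decisions(self, smiles, expected):
        assert exclude_structure(smiles) == expected


class TestActivityNormalization:
    def test_imputation(self):
        rec = make_record(activity_type="qualitative_inactive", activity_value=None)
        assert impute_qualitative_inactive(rec).activity_value == 1000.0

    def test_imputation_is_noop_with_value(self):
        rec = make_record(activity_value=5.0)
        assert impute_qualitative_inactive(rec) is rec

    def test_imputed_ratio_against_default_control(self):
        rec = impute_qualitative_inactive(
            make_record(activity_type="qualitative_inactive", activity_value=None)
        )
        assert normalize_activity(rec.activity_value, 20.0) == 50.0

    @pytest.mark.parametrize(
        "value,control,expected", [(40, 20, 2.0), (10, None, 0.5), (20, 20, 1.0)]
    )
    def test_ratio(self, value, control, expected):
        assert normalize_activity(value, control) == expected

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_activity(10.0, 0.0)

    @given(
        value=st.floats(1e-3, 1e6),
        control=st.floats(1e-3, 1e4),
        factor=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_consistency(self, value, control, factor):
        base = normalize_activity(value, control)
        scaled = normalize_activity(value * factor, control * factor)
        assert scaled == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize(
        "ratio,expected", [(0.5, "active"), (1.0, "inactive"), (50.0, "inactive")]
    )
    def test_classification_boundary(self, ratio, expected):
        assert classify_activity(ratio) == expected


class TestDeduplicate:
    def _normalized(self, rows):
        records = [make_record(**row) for row in rows]
        normalized, rejects = normalize_records(records)
        assert rejects.empty
        return normalized

    def test_keeps_most_potent(self):
        normalized = self._normalized(
            [
                dict(record_id="a", activity_value=40.0),  # ratio 2.0
                dict(record_id="b", activity_value=6.0, reference_id="ref2"),  # 0.3
            ]
        )
        curated = deduplicate(normalized)
        assert len(curated) == 1
        assert curated.iloc[0]["ratio"] == pytest.approx(0.3)
        assert curated.iloc[0]["n_merged"] == 2

    def test_singleton_passthrough(self):
        curated = deduplicate(self._normalized([dict(record_id="a")]))
        assert curated.iloc[0]["n_merged"] == 1
        assert curated.iloc[0]["ratio"] == pytest.approx(0.5)

    def test_ratio_tie_broken_by_reference_id(self):
        normalized = self._normalized(
            [
                dict(record_id="a", reference_id="zz", year=2001),
                dict(record_id="b", reference_id="aa", year=2005),
            ]
        )
        curated = deduplicate(normalized)
        # both ratios equal; the 'aa' record wins, but first_year is the min
        assert curated.iloc[0]["first_year"] == 2001

    def test_species_union_and_first_year(self):
        normalized = self._normalized(
            [
                dict(record_id="a", species="sp1", year=2010),
                dict(record_id="b", species="sp2", year=2003, reference_id="r2"),
            ]
        )
        row = deduplicate(normalized).iloc[0]
        assert row["species"] == "sp1;sp2"
        assert row["first_year"] == 2003

    def test_idempotent(self, noiseless_curated):
        curated, normalized, _ = noiseless_curated
        again = deduplicate(normalized)
        pd.testing.assert_frame_equal(curated, again)
        # dedup of an already-unique table changes nothing
        renorm = normalized.drop_duplicates("inchikey", keep="first")
        once = deduplicate(renorm)
        twice = deduplicate(
            once.rename(columns={"best_value_um": "value_um"}).assign(
                record_id="x", year=once["first_year"], reference_id="x"
            )[curation.NORMALIZED_COLUMNS]
        )
        assert list(once["inchikey"]) == list(twice["inchikey"])
        assert np.allclose(once["ratio"], twice["ratio"])

    def test_full_accounting(self, noiseless_library, noiseless_curated):
        _, records, _ = noiseless_library
        curated, normalized, rejects = noiseless_curated
        assert len(normalized) + len(rejects) == len(records)
        assert set(curated["inchikey"]) == set(normalized["inchikey"])

    def test_class_consistent_with_ratio(self, noiseless_curated):
        curated, _, _ = noiseless_curated
        recomputed = curated["ratio"].map(classify_activity)
        assert (recomputed == curated["activity_class"]).all()

    def test_output_sorted_by_inchikey(self, noiseless_curated):
        curated, _, _ = noiseless_curated
        assert list(curated["inchikey"]) == sorted(curated["inchikey"])


class TestRawCsvIO:
    def test_unit_conversion_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            [
                ["r1", "CCO", 500, "nM", "IC50", 0.02, "mM", "sp", 2010, "ref1"],
                ["r2", "CCN", 1, "uM", "Ki", None, None, "sp", None, "ref2"],
            ],
            columns=curation.RAW_CSV_COLUMNS,
        )
        path = tmp_path / "raw.csv"
        df.to_csv(path, index=False)
        records = read_raw_csv(path)
        assert records[0].activity_value == pytest.approx(0.5)
        assert records[0].control_value == pytest.approx(20.0)
        assert records[1].control_value is None
        assert records[1].year is None

    def test_unknown_unit_rejected(self, tmp_path):
        df = pd.DataFrame(
            [["r1", "CCO", 1, "pM", "IC50", None, None, "sp", 2010, "ref"]],
            columns=curation.RAW_CSV_COLUMNS,
        )
        path = tmp_path / "raw.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="unit"):
            read_raw_csv(path)


def test_curate_rejects_are_logged_not_raised():
    records = [
        make_record(record_id="good"),
        make_record(record_id="metal", smiles="[Ni](Cl)(Cl)"),
        make_record(record_id="bad", smiles=")("),
    ]
    curated, normalized, rejects = curate(records)
    assert len(curated) == 1
    assert sorted(rejects["reason"]) == ["metal_complex", "parse_error"]
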
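"""Loading mixed tables and the IF fuzzification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifrmi.ifis import (
    AttributeSchema,
    IFValue,
    MixedDataset,
    intuitionistic_fuzzify,
    load_schema_sidecar,
    load_table,
    validate_ifis,
)

SCHEMA3 = (
    AttributeSchema("a", "numeric"),
    AttributeSchema("b", "nominal"),
    AttributeSchema("d", "nominal", "decision"),
)


def write_csv(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadTable:
    def test_round_trip_well_formed_csv(self, tmp_path):
        p = write_csv(tmp_path, "a,b,d\n1.5,p,A\n2.5,q,A\n3.5,p,B\n")
        data = load_table(p, SCHEMA3)
        assert data.n == 3
        assert len(data.conditional_attributes) == 2
        assert list(data.frame["a"]) == [1.5, 2.5, 3.5]
        assert list(data.decision_labels()) == ["A", "A", "B"]

    def test_missing_cell_rejected_and_located(self, tmp_path):
        p = write_csv(tmp_path, "a,b,d\n1.5,p,A\n,q,A\n3.5,p,B\n")
        with pytest.raises(ValueError, match=r"row 1, column 'a'"):
            load_table(p, SCHEMA3)

    def test_missing_cell_imputed_when_enabled(self, tmp_path):
        p = write_csv(tmp_path, "a,b,d\n1.0,p,A\n,q,A\n3.0,p,B\n")
        data = load_table(p, SCHEMA3, impute=True)
        assert data.frame["a"].iloc[1] == pytest.approx(2.0)

    def test_schema_name_absent_from_header(self, tmp_path):
        p = write_csv(tmp_path, "a,b,d\n1,p,A\n")
        bad = SCHEMA3[:2] + (AttributeSchema("zzz", "nominal", "decision"),)
        with pytest.raises(ValueError, match="zzz"):
            load_table(p, bad)

    def test_non_numeric_token_rejected(self, tmp_path):
        p = write_csv(tmp_path, "a,b,d\noops,p,A\n2,q,B\n")
        with pytest.raises(ValueError):
            load_table(p, SCHEMA3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_table(tmp_path / "nope.csv", SCHEMA3)

    def test_yaml_sidecar(self, tmp_path):
        p = write_csv(tmp_path, "a,b,d\n1,p,A\n2,q,B\n")
        sidecar = tmp_path / "data.schema.yaml"
        sidecar.write_text(
            "a: {kind: numeric, role: conditional}\n"
            "b: {kind: nominal, role: conditional}\n"
            "d: {kind: nominal, role: decision}\n"
        )
        data = load_table(p, sidecar)
        assert [a.name for a in data.schema] == ["a", "b", "d"]
        assert load_schema_sidecar(sidecar) == data.schema

    def test_arff_kinds_and_decision(self, tmp_path):
        p = tmp_path / "toy.arff"
        p.write_text(
            "@relation toy\n"
            "@attribute a numeric\n"
            "@attribute b {p,q}\n"
            "@attribute class {A,B}\n"
            "@data\n1.0,p,A\n2.0,q,B\n"
        )
        data = load_table(p)
        kinds = {a.name: a.kind for a in data.schema}
        assert kinds == {"a": "numeric", "b": "nominal", "class": "nominal"}
        assert data.decision_name == "class"

    def test_two_decision_attributes_rejected(self):
        schema = (
            AttributeSchema("a", "numeric", "decision"),
            AttributeSchema("d", "nominal", "decision"),
        )
        with pytest.raises(ValueError, match="exactly one decision"):
            MixedDataset(frame=pd.DataFrame({"a": [1.0], "d": ["A"]}), schema=schema)


class TestFuzzify:
    def test_minmax_endpoints_and_midpoint(self, make_ifis):
        ifis = make_ifis({"a": [2.0, 4.0, 6.0], "d": ["A", "A", "B"]},
                         {"d": "nominal"})
        np.testing.assert_allclose(ifis.mu["a"], [0.0, 0.5, 1.0])

    def test_sugeno_complement_values(self, make_ifis):
        ifis = make_ifis({"a": [2.0, 4.0, 6.0], "d": ["A", "A", "B"]},
                         {"d": "nominal"}, lam=1.0)
        # mu=0.5 -> nu=(1-0.5)/(1+0.5)=1/3; boundaries mu=1->nu=0, mu=0->nu=1
        np.testing.assert_allclose(ifis.nu["a"], [1.0, 1.0 / 3.0, 0.0])
        assert np.all(ifis.mu["a"] + ifis.nu["a"] <= 1 + 1e-12)

    def test_constant_column_maps_to_half(self, make_ifis):
        ifis = make_ifis({"a": [3.0, 3.0, 3.0], "d": ["A", "B", "A"]},
                         {"d": "nominal"})
        np.testing.assert_allclose(ifis.mu["a"], 0.5)

    def test_nominal_passthrough_first_appearance_codes(self, make_ifis):
        ifis = make_ifis({"b": ["q", "p", "q"], "d": ["A", "A", "B"]},
                         {"b": "nominal", "d": "nominal"})
        np.testing.assert_array_equal(ifis.codes["b"], [0, 1, 0])

    def test_nonpositive_lambda_rejected(self, make_ifis):
        with pytest.raises(ValueError, match="lambda"):
            make_ifis({"a": [1.0, 2.0], "d": ["A", "B"]}, {"d": "nominal"}, lam=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20, unique=True),
        st.floats(0.1, 10.0),
    )
    def test_invariants_order_and_affine_invariance(self, values, lam):
        frame = pd.DataFrame({"a": values, "d": ["A"] * len(values)})
        schema = (AttributeSchema("a", "numeric"),
                  AttributeSchema("d", "nominal", "decision"))
        ifis = intuitionistic_fuzzify(MixedDataset(frame=frame, schema=schema), lam)
        mu, nu = ifis.mu["a"], ifis.nu["a"]
        assert np.all(mu + nu <= 1 + 1e-12)
        assert np.all((1 - mu - nu) >= -1e-12)
        order = np.argsort(values)
        assert np.all(np.diff(mu[order]) >= -1e-12)
        assert np.all(np.diff(nu[order]) <= 1e-12)
        # affine rescale leaves mu unchanged
        frame2 = frame.assign(a=np.asarray(values) * 3.5 + 11.0)
        ifis2 = intuitionistic_fuzzify(MixedDataset(frame=frame2, schema=schema), lam)
        np.testing.assert_allclose(ifis2.mu["a"], mu, atol=1e-12)


class TestValidateIFIS:
    def test_fuzzified_system_is_clean(self, random_system):
        assert validate_ifis(random_system(3)) == []

    def test_broken_values_flagged_with_location(self, fixture_ifis):
        fixture_ifis.mu["a"] = np.array([0.7, -0.1, 0.5])
        fixture_ifis.nu["a"] = np.array([0.5, 0.2, 0.4])
        report = validate_ifis(fixture_ifis)
        assert any(r[0] == 0 and r[1] == "a" and "> 1" in r[2] for r in report)
        assert any(r[0] == 1 and "outside" in r[2] for r in report)

    def test_ifvalue_violation_messages(self):
        assert IFValue(0.7, 0.5).violations()
        assert IFValue(-0.1, 0.2).violations()
        assert IFValue(0.3, 0.3).violations() == []
        assert IFValue(0.3, 0.3).pi == pytest.approx(0.4)
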
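"""Polynomial-network evaluator, frozen published model, and trainer."""

import numpy as np
import pytest

from silkspin.dataset import load_table1, split_dataset
from silkspin.evaluation import mard
from silkspin.gmdh import (
    GmdhConfig,
    GmdhFitError,
    ModelStructureError,
    MonomialTerm,
    PolyNeuron,
    PolynomialModel,
    evaluate,
    evaluate_many,
    export_polynomial,
    fit_gmdh,
    frozen_table2_model,
    parse_polynomial,
)
from silkspin.synth import GroundTruth, generate_dataset


def direct_published_polynomial(c_pct, flow, volt, dist, speed):
    """Independent arithmetic oracle: the published two-layer polynomial
    written out longhand, concentration as mass fraction."""
    x1, x2, x3, x4, x5 = c_pct / 100.0, flow, volt, dist, speed
    n1 = (57.899 - 0.978409 * x4 - 0.0118487 * x5 + 502124 * x1**4
          + 144.964 * x2 + 0.0842974 * x3**2)
    return (-84.2446 + 0.00342148 * x5 - 24.1294 * x2 + 100.383 * x2**4
            + 1.65187 * n1 - 4.80264e-6 * n1**3)


@pytest.fixture(scope="module")
def frozen():
    return frozen_table2_model()


@pytest.fixture(scope="module")
def table1():
    return load_table1()


class TestFrozenModelStructure:
    def test_one_hidden_layer_with_one_neuron(self, frozen):
        assert frozen.n_layers == 1
        assert len(frozen.layers[0]) == 1

    def test_hidden_neuron_has_six_terms_with_constant(self, frozen):
        n1 = frozen.layers[0][0]
        assert n1.name == "N1"
        assert len(n1.terms) == 6
        constants = [t.coefficient for t in n1.terms if not any(t.exponents)]
        assert constants == [57.899]

    def test_output_references_speed_flow_and_hidden(self, frozen):
        assert set(frozen.output.input_refs) == {"X5", "X2", "N1"}

    def test_concentration_encoded_as_fraction(self, frozen):
        assert frozen.input_encoding[0] == (0.01, 0.0)


class TestEvaluate:
    def test_matches_direct_arithmetic_on_all_29(self, frozen, table1):
        expected = [direct_published_polynomial(*s.covariates()) for s in table1]
        got = evaluate_many(frozen, table1)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_sample1_prediction_near_measurement(self, frozen, table1):
        pred = evaluate(frozen, table1.samples[0])
        assert pred == pytest.approx(135.145, abs=0.01)
        assert abs(pred - 134.19) / 134.19 < 0.05

    def test_all_29_deviations_below_15pct(self, frozen, table1):
        rel = np.abs(evaluate_many(frozen, table1) - table1.diameters())
        assert np.max(rel / table1.diameters()) < 0.15

    def test_constant_model_returns_constant(self, table1):
        model = PolynomialModel(
            layers=(),
            output=PolyNeuron("d", ("X1",), (MonomialTerm((0,), 42.5),)),
        )
        assert evaluate(model, table1.samples[7]) == pytest.approx(42.5)

    def test_term_order_irrelevant(self, frozen, table1):
        n1 = frozen.layers[0][0]
        shuffled = PolyNeuron(n1.name, n1.input_refs, tuple(reversed(n1.terms)))
        model = PolynomialModel((( shuffled,),), frozen.output, frozen.input_encoding)
        assert evaluate_many(model, table1) == pytest.approx(
            evaluate_many(frozen, table1), rel=1e-12
        )

    def test_unresolved_reference_rejected(self):
        bad_out = PolyNeuron("d", ("N9",), (MonomialTerm((1,), 1.0),))
        with pytest.raises(ModelStructureError, match="N9"):
            PolynomialModel(layers=(), output=bad_out)


class TestFrozenModelTrends:
    """Grid scans of the published polynomial reproduce the reported
    qualitative responses: diameter rises with flow rate, falls with
    spinning distance and with collector speed."""

    def _scan(self, frozen, base, index, grid):
        cov = np.tile(base, (grid.size, 1))
        cov[:, index] = grid
        return evaluate_many(frozen, cov)

    def test_increasing_with_flow_rate(self, frozen):
        base = np.array([10.0, 0.0, 20.0, 12.0, 200.0])
        preds = self._scan(frozen, base, 1, np.linspace(0.1, 0.6, 200))
        assert np.all(np.diff(preds) > 0)

    def test_decreasing_with_distance(self, frozen):
        base = np.array([10.0, 0.4, 20.0, 0.0, 200.0])
        preds = self._scan(frozen, base, 3, np.linspace(8.0, 12.0, 200))
        assert np.all(np.diff(preds) < 0)

    def test_decreasing_with_collector_speed(self, frozen):
        base = np.array([10.0, 0.4, 20.0, 12.0, 0.0])
        preds = self._scan(frozen, base, 4, np.linspace(200.0, 2500.0, 200))
        assert np.all(np.diff(preds) < 0)


class TestFit:
    def test_recovers_polynomial_ground_truth_exactly(self):
        """Noiseless data from a truth inside the candidate family is
        reproduced to the numerical floor, with matching coefficients."""
        truth = GroundTruth(
            terms=(((0, 0, 0, 0, 0), 3.0), ((0, 1, 0, 0, 0), 2.0),
                   ((0, 0, 2, 0, 0), 0.08))
        )
        data = generate_dataset(truth, n=40, seed=3)
        model = fit_gmdh(data, GmdhConfig(seed=1))
        mse = np.mean((evaluate_many(model, data) - data.diameters()) ** 2)
        assert mse < 1e-10
        coefs = _grand_coefficients(model)
        assert coefs.pop(("const",)) == pytest.approx(3.0, rel=1e-6)
        assert coefs.pop(("X2", 1)) == pytest.approx(2.0, rel=1e-6)
        assert coefs.pop(("X3", 2)) == pytest.approx(0.08, rel=1e-6)
        assert all(abs(c) < 1e-8 for c in coefs.values())

    def test_constant_response_gives_constant_model(self):
        data = generate_dataset(GroundTruth.constant(150.0), n=20, seed=5)
        model = fit_gmdh(data, GmdhConfig(seed=0))
        preds = evaluate_many(model, data)
        assert preds == pytest.approx([150.0] * 20, rel=1e-9)
        coefs = _grand_coefficients(model)
        assert coefs.pop(("const",)) == pytest.approx(150.0, rel=1e-9)
        assert all(abs(c) < 1e-8 for c in coefs.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_design_table_held_out_accuracy(self, table1, seed):
        """70/30 training on the 29-run design generalizes to the held-out
        runs at single-digit MARD."""
        split = split_dataset(table1, 0.7, seed=seed)
        model = fit_gmdh(table1.subset(split.train_ids), GmdhConfig(seed=seed))
        test = table1.subset(split.test_ids)
        report = mard(test.diameters(), evaluate_many(model, test))
        assert report.mard_percent <= 10.0

    def test_deterministic_under_seed(self):
        truth = GroundTruth(
            terms=(((0, 0, 0, 0, 0), 100.0), ((0, 0, 0, 1, 0), -3.0)),
            noise_sd=5.0,
        )
        data = generate_dataset(truth, n=30, seed=8)
        a = fit_gmdh(data, GmdhConfig(seed=4))
        b = fit_gmdh(data, GmdhConfig(seed=4))
        assert a.to_dict() == b.to_dict()

    def test_diameterless_data_rejected(self):
        data = generate_dataset(GroundTruth.constant(150.0), n=20, seed=5)
        from silkspin.dataset import Dataset, ElectrospinningSample

        stripped = Dataset(
            tuple(
                ElectrospinningSample(s.sample_id, s.concentration, s.flow_rate,
                                      s.voltage, s.distance, s.collector_speed)
                for s in data
            )
        )
        with pytest.raises(GmdhFitError):
            fit_gmdh(stripped, GmdhConfig())

    def test_too_few_samples_rejected(self):
        data = generate_dataset(GroundTruth.constant(150.0), n=5, seed=5)
        with pytest.raises(GmdhFitError):
            fit_gmdh(data, GmdhConfig(max_terms_per_neuron=6))


def _grand_coefficients(model: PolynomialModel) -> dict:
    """Map term signature -> coefficient for a model whose output refers
    only to covariates (single-neuron models from recovery tests)."""
    assert model.n_layers == 0
    out = {}
    for t in model.output.terms:
        if not any(t.exponents):
            out[("const",)] = out.get(("const",), 0.0) + t.coefficient
            continue
        active = [(model.output.input_refs[j], e)
                  for j, e in enumerate(t.exponents) if e]
        assert len(active) == 1  # pure-power family
        out[active[0]] = out.get(active[0], 0.0) + t.coefficient
    return out


class TestExportParse:
    def test_frozen_model_text_contains_published_coefficients(self, frozen):
        text = export_polynomial(frozen)
        assert "57.899" in text
        assert "-84.2446" in text

    def test_parse_inverts_export(self, frozen, table1):
        text = export_polynomial(frozen)
        back = parse_polynomial(text)
        assert evaluate_many(back, table1) == pytest.approx(
            evaluate_many(frozen, table1), rel=1e-12
        )

    def test_export_parse_export_fixed_point(self, frozen):
        text = export_polynomial(frozen)
        assert export_polynomial(parse_polynomial(text)) == text

    def test_constant_model_single_term_text(self):
        model = PolynomialModel(
            layers=(), output=PolyNeuron("d", ("X1",), (MonomialTerm((0,), 5.0),))
        )
        line = export_polynomial(model).strip().splitlines()[-1]
        assert line == "d = 5"

    def test_json_round_trip(self, frozen, table1, tmp_path):
        path = tmp_path / "model.json"
        frozen.save(path)
        back = PolynomialModel.load(path)
        assert back.to_dict() == frozen.to_dict()
        assert evaluate_many(back, table1) == pytest.approx(
            evaluate_many(frozen, table1), rel=1e-15
        )
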
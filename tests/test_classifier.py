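import numpy as np
import pytest

from subspec.classifier import (
    ModelLibrary,
    SynonymMap,
    build_ensemble_library,
    build_single_library,
    classify,
)
from subspec.io_formats import AMINO_ACIDS, DomainSequence, MultipleAlignment
from subspec.njtree import CladePartition


def _groups(sizes: dict[str, int], length: int = 30, seed: int = 0):
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out = {}
    for substrate, n in sizes.items():
        base = aa[rng.integers(0, 20, length)]
        rows = []
        for _ in range(n):
            row = base.copy()
            mask = rng.random(length) < 0.1
            row[mask] = aa[rng.integers(0, 20, int(mask.sum()))]
            rows.append("".join(row))
        out[substrate] = MultipleAlignment(
            [f"{substrate}_{i}" for i in range(n)], rows
        )
    return out


class TestSingleLibrary:
    def test_singletons_excluded_and_reported(self):
        groups = _groups({"a": 5, "b": 2, "c": 1})
        library, excluded = build_single_library(groups, "AT")
        assert len(library.models) == 2
        assert excluded == ["c"]
        assert library.mode == "single"
        assert library.threshold_bits == 325.0  # AT default

    def test_no_qualifying_group_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_single_library(_groups({"a": 1}), "A")

    def test_a_domain_threshold_default(self):
        library, _ = build_single_library(_groups({"a": 2, "b": 2}), "A")
        assert library.threshold_bits == 625.0


class TestEnsembleLibrary:
    def test_partitioned_substrates_get_one_model_per_part(self):
        groups = _groups({"big": 12, "small": 3})
        ids = groups["big"].ids
        partition = CladePartition("big", [ids[:6], ids[6:]], ["p1", "p2"])
        library, _ = build_ensemble_library(
            groups, "AT", {"big": partition}, size_threshold=10
        )
        big_models = library.models_for("big")
        assert [m.name for m in big_models] == ["big_1", "big_2"]
        assert [m.subgroup_index for m in big_models] == [1, 2]
        assert len(library.models_for("small")) == 1

    def test_below_size_threshold_falls_back_to_single_model(self):
        groups = _groups({"x": 9, "y": 3})
        ids = groups["x"].ids
        partition = CladePartition("x", [ids[:4], ids[4:]], ["p1", "p2"])
        library, _ = build_ensemble_library(
            groups, "AT", {"x": partition}, size_threshold=10
        )
        assert len(library.models_for("x")) == 1

    def test_ensemble_never_smaller_than_single(self):
        groups = _groups({"big": 12, "small": 3, "solo": 1})
        ids = groups["big"].ids
        partition = CladePartition("big", [ids[:6], ids[6:]], ["p1", "p2"])
        single, _ = build_single_library(groups, "AT")
        ensemble, _ = build_ensemble_library(
            groups, "AT", {"big": partition}, size_threshold=10
        )
        assert len(ensemble.models) >= len(single.models)

    def test_unknown_partition_ids_rejected(self):
        groups = _groups({"big": 12})
        partition = CladePartition("big", [["nope1"], ["nope2"]], ["p1", "p2"])
        with pytest.raises(ValueError, match="unknown ids"):
            build_ensemble_library(groups, "AT", {"big": partition}, size_threshold=10)


class TestClassify:
    def test_deterministic_and_pure(self):
        groups = _groups({"a": 3, "b": 3})
        library, _ = build_single_library(groups, "AT", threshold_bits=0.0)
        seq = DomainSequence("q", groups["a"].rows[0], "AT")
        p1 = classify(library, seq)
        p2 = classify(library, seq)
        assert p1 == p2
        assert p1.predicted_substrate == "a"

    def test_threshold_flips_reliability_not_prediction(self):
        groups = _groups({"a": 3, "b": 3})
        low, _ = build_single_library(groups, "AT", threshold_bits=0.0)
        high, _ = build_single_library(groups, "AT", threshold_bits=1e9)
        seq = DomainSequence("q", groups["a"].rows[0], "AT")
        pl, ph = classify(low, seq), classify(high, seq)
        assert pl.predicted_substrate == ph.predicted_substrate
        assert pl.reliable and not ph.reliable
        assert pl.bit_score == ph.bit_score

    def test_all_x_sequence_is_unreliable(self):
        groups = _groups({"a": 3, "b": 3})
        library, _ = build_single_library(groups, "AT", threshold_bits=1.0)
        pred = classify(library, DomainSequence("q", "X" * 30, "AT"))
        assert not pred.reliable

    def test_runner_up_recorded(self):
        groups = _groups({"a": 3, "b": 3})
        library, _ = build_single_library(groups, "AT", threshold_bits=0.0)
        pred = classify(library, DomainSequence("q", groups["a"].rows[0], "AT"))
        assert pred.runner_up is not None
        assert pred.runner_up[0] != pred.best_model
        assert pred.runner_up[1] <= pred.bit_score

    def test_ensemble_recovers_convergent_minority_clade(
        self, convergent_ds, convergent_libraries
    ):
        single, ensemble, _ = convergent_libraries
        minority = convergent_ds.clade_members("S1/minor")
        seqs = {s.id: s for s in convergent_ds.sequences}
        ens_ok = sum(
            classify(ensemble, seqs[m]).predicted_substrate == "S1"
            and classify(ensemble, seqs[m]).reliable
            for m in minority
        )
        single_ok = sum(
            classify(single, seqs[m]).predicted_substrate == "S1"
            and classify(single, seqs[m]).reliable
            for m in minority
        )
        assert ens_ok == len(minority)
        assert single_ok < ens_ok


class TestLibraryConstraints:
    def test_single_mode_allows_one_model_per_substrate(self):
        groups = _groups({"a": 4})
        library, _ = build_single_library(groups, "AT")
        extra = library.models[0]
        with pytest.raises(ValueError, match="exceeds"):
            ModelLibrary("AT", [extra, extra], "single", 0.0)


class TestSynonymMap:
    def test_shipped_groups(self):
        syn = SynonymMap()
        assert syn.equivalent("dhb", "sal")
        assert syn.equivalent("thr", "allo-thr")
        assert syn.equivalent("hpg", "hpg2Cl")
        assert not syn.equivalent("dhb", "thr")
        assert syn.equivalent("ala", "ala")
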
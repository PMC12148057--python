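import json

import numpy as np
import pandas as pd
import pytest

from scadvisor._errors import MetricError, ParseError, UserError
from scadvisor import assistant
from scadvisor.assistant import (
    FilterCutoffs,
    ResolutionRange,
    run_task,
)
from scadvisor.assistant.network import graph_from_text, write_html
from scadvisor.backends import make_replay_backend
from scadvisor.dataio import CELL_TYPE_COLUMN, GeneSetCollection
from scadvisor.prompt_engine import TASK_IDS
from scadvisor.synth import (
    SynthConfig,
    build_fixture_store,
    generate_counts,
    generate_marker_table,
    planted_markers,
)


def test_registry_has_all_ten_tasks():
    assert set(assistant.TASK_REGISTRY) == set(TASK_IDS)


def test_unknown_task():
    with pytest.raises(UserError, match="unknown task"):
        run_task("foo", None, None)


# ---------------------------------------------------------------------------
# run_task per task
# ---------------------------------------------------------------------------

def test_recommend_res_parses_example_payload(synth_ds, replay_cfg):
    rec = run_task("recommend_res", synth_ds, replay_cfg)
    assert rec.parse_error is None
    payload = rec.parsed_payload
    assert isinstance(payload, ResolutionRange)
    assert (payload.start, payload.stop, payload.step) == (0.2, 1.2, 0.1)
    assert "heterogeneity" in payload.reasoning


def test_quality_cutoffs_payload(synth_ds, replay_cfg):
    rec = run_task("analyze_quality", synth_ds, replay_cfg)
    assert rec.parse_error is None
    assert isinstance(rec.parsed_payload, FilterCutoffs)
    assert rec.parsed_payload.bounds["n_genes_detected"] == (200, 5000)
    assert rec.parsed_payload.bounds["total_counts"] == (500, 30000)


def test_quality_prompt_contains_metrics(synth_ds, replay_cfg):
    rec = run_task("analyze_quality", synth_ds, replay_cfg)
    assert str(synth_ds.n_cells) in rec.rendered_prompt
    assert "total_counts" in rec.rendered_prompt
    assert "quantiles" in rec.rendered_prompt


def test_unparseable_response_flagged_not_raised(synth_ds, fixture_store):
    store = dict(fixture_store)
    store["recommend_k"] = {"default": "pick whatever feels right"}
    cfg = make_replay_backend(store)
    rec = run_task("recommend_k", synth_ds, cfg)
    assert rec.parse_error is not None
    assert rec.raw_response == "pick whatever feels right"
    assert rec.parsed_payload is None


def test_metric_error_carries_task_context(replay_cfg):
    from scadvisor.dataio import CellDataset

    empty = CellDataset.from_counts(np.zeros((3, 2), dtype=int), ["a", "b"])
    with pytest.raises(MetricError, match=r"\[recommend_normalization\]"):
        run_task("recommend_normalization", empty, replay_cfg)


def test_record_display_includes_reasoning(synth_ds, replay_cfg):
    rec = run_task("recommend_res", synth_ds, replay_cfg)
    assert "Reasoning" in rec.raw_response


@pytest.mark.parametrize("task_id", [
    "recommend_normalization", "analyze_variable_features",
    "recommend_pcs", "analyze_pcs", "recommend_k",
])
def test_metric_tasks_run_green(task_id, synth_ds, replay_cfg):
    rec = run_task(task_id, synth_ds, replay_cfg)
    assert rec.parse_error is None
    assert rec.raw_response


def test_recommend_k_payload(synth_ds, replay_cfg):
    rec = run_task("recommend_k", synth_ds, replay_cfg)
    assert rec.parsed_payload == {"k_min": 10, "k_max": 30}


def test_recommend_pcs_payload(synth_ds, replay_cfg):
    rec = run_task("recommend_pcs", synth_ds, replay_cfg)
    assert rec.parsed_payload == {"n_pcs": 10}


def test_normalization_payload(synth_ds, replay_cfg):
    rec = run_task("recommend_normalization", synth_ds, replay_cfg)
    assert rec.parsed_payload["method"] == "LogNormalize"


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def annotate_setup():
    ds = generate_counts(SynthConfig(n_cells=150, n_genes=300, seed=5))
    table = generate_marker_table(ds)
    return ds, table


def test_annotate_no_apply_leaves_dataset(annotate_setup, replay_cfg):
    ds, table = annotate_setup
    before = ds.cell_meta.copy()
    record, out = assistant.analyze_and_annotate(ds, table, replay_cfg, apply=False)
    assert record.parse_error is None
    assert out is ds
    pd.testing.assert_frame_equal(ds.cell_meta, before)


def test_annotate_apply_labels_every_cell(annotate_setup, replay_cfg):
    ds, table = annotate_setup
    record, out = assistant.analyze_and_annotate(ds, table, replay_cfg, apply=True)
    assert record.parse_error is None
    labels = out.cell_meta[CELL_TYPE_COLUMN]
    assert labels.notna().all()
    assert set(labels.unique()) == {"NK cells", "CD8 T cells", "B cells"}


def test_annotate_atomic_on_corrupted_fixture(annotate_setup, fixture_store):
    ds, table = annotate_setup
    store = dict(fixture_store)
    store["analyze_and_annotate"] = {"default": "Cluster 0: NK cells"}  # misses 1,2
    cfg = make_replay_backend(store)
    record, out = assistant.analyze_and_annotate(ds, table, cfg, apply=True)
    assert record.parse_error is not None
    assert out is ds
    assert CELL_TYPE_COLUMN not in ds.cell_meta.columns


# ---------------------------------------------------------------------------
# enrichment + network
# ---------------------------------------------------------------------------

def test_enrichment_planted_set_ranks_first(replay_cfg):
    cfg = SynthConfig(n_cells=120, n_genes=250, seed=9)
    ds = generate_counts(cfg)
    planted = planted_markers(cfg)["0"]
    rng = np.random.default_rng(0)
    decoys = [g for g in ds.gene_names if g not in planted]
    sets = GeneSetCollection(
        sets={
            "PLANTED": set(planted),
            "DECOY_1": set(rng.choice(decoys, 15, replace=False)),
            "DECOY_2": set(rng.choice(decoys, 25, replace=False)),
        }
    )
    record, table = assistant.analyze_enrichment(
        planted, sets, replay_cfg, ds=ds
    )
    assert len(table) >= 1
    assert table.rows.loc[0, "set_name"] == "PLANTED"
    assert record.parse_error is None


def test_enrichment_empty_table_prompt_states_it(replay_cfg):
    universe = [f"g{i}" for i in range(50)]
    sets = GeneSetCollection(sets={"S": set(universe[40:])})
    record, table = assistant.analyze_enrichment(
        universe[:5], sets, replay_cfg, universe_genes=universe
    )
    assert len(table) == 0
    assert "No significant enrichment" in record.rendered_prompt


def test_summary_network_from_fixture(replay_cfg, tmp_path):
    from scadvisor.dataio import RecommendationRecord

    base = RecommendationRecord(
        task_id="analyze_enrichment",
        rendered_prompt="p",
        raw_response="TNF drives NFKB1 which drives IL6",
    )
    record, net = assistant.summary_network(
        base, replay_cfg, html_out=tmp_path / "net.html"
    )
    assert len(net.nodes) == 4
    assert len(net.edges) == 3
    html = (tmp_path / "net.html").read_text()
    assert "TNF" in html and "<svg" in html


def test_summary_network_zero_edges_errors(fixture_store):
    from scadvisor.dataio import RecommendationRecord

    store = dict(fixture_store)
    store["summary_network"] = {"default": "no edges to speak of"}
    cfg = make_replay_backend(store)
    base = RecommendationRecord(
        task_id="analyze_enrichment", rendered_prompt="p", raw_response="x"
    )
    with pytest.raises(ParseError):
        with pytest.warns(UserWarning):
            assistant.summary_network(base, cfg)


def test_network_typing_and_counts():
    net = graph_from_text(
        "TNF|activates|NFKB1\nNFKB1|regulates|IL6\n"
        "IL6|member of|inflammatory response pathway"
    )
    assert net.node_type("TNF") == "regulator"
    assert net.node_type("inflammatory response pathway") == "pathway"
    assert net.node_type("IL6") in ("gene/target", "regulator")


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def _record_bytes(rec):
    d = rec.to_dict()
    d["timestamp"] = ""
    return json.dumps(d, sort_keys=True, default=str).encode()


def test_run_task_deterministic(replay_cfg):
    def one_run():
        ds = generate_counts(SynthConfig(n_cells=100, n_genes=200, seed=3))
        return run_task("recommend_res", ds, replay_cfg)

    assert _record_bytes(one_run()) == _record_bytes(one_run())
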
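import math
from dataclasses import replace

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from sncdev.morphology import (
    DENDRITE,
    MorphologyError,
    NeuronMorphology,
    SectionNode,
    UndefinedMetric,
    apply_taper,
    count_segments,
    equivalent_cylinder,
    identify_abd,
    load_morphology,
    save_morphology,
    summarize,
)
from sncdev.synthetic import default_stage_params, sample_neuron

from conftest import make_soma


# ---------------------------------------------------------------------------
# independent oracle: segments as maximal unbranched chains of the dendritic
# skeleton graph
# ---------------------------------------------------------------------------

def segment_count_oracle(m, subset="all"):
    abd = identify_abd(m)
    abd_ids = set(m.subtree(abd)) if abd is not None else set()
    g = nx.Graph()
    for s in m.sections.values():
        if s.label != DENDRITE:
            continue
        if subset == "abd" and s.id not in abd_ids:
            continue
        if subset == "nabd" and s.id in abd_ids:
            continue
        parent = m.sections[s.parent]
        pnode = "soma" if parent.label != DENDRITE else f"end:{parent.id}"
        g.add_edge(pnode, f"end:{s.id}", sid=s.id)
    # smooth out degree-2 interior nodes; the soma never merges chains
    n = 0
    seen = set()
    for u, v, d in g.edges(data=True):
        if d["sid"] in seen:
            continue
        # walk both directions until a node of degree != 2 or the soma
        chain = {d["sid"]}
        frontier = [(u, (u, v)), (v, (u, v))]
        while frontier:
            node, edge = frontier.pop()
            if node == "soma" or g.degree(node) != 2:
                continue
            for w in g.neighbors(node):
                e = tuple(sorted((node, w)))
                sid = g.edges[node, w]["sid"]
                if sid not in chain:
                    chain.add(sid)
                    frontier.append((w, (node, w)))
        seen |= chain
        n += 1
    return n


def random_tree_morph(rng, n_extra=8, subdivide=0.0):
    secs = {"soma": make_soma()}
    ids = []
    for i in range(n_extra):
        parent = "soma" if not ids or rng.random() < 0.3 else \
            ids[rng.integers(len(ids))]
        sid = f"d{i}"
        secs[sid] = SectionNode(sid, DENDRITE, parent,
                                float(rng.uniform(5, 50)), 1.0, 1.0)
        ids.append(sid)
    m = NeuronMorphology(secs, 1000.0)
    if subdivide:
        for sid in list(m.sections):
            if m.sections[sid].label == DENDRITE and rng.random() < subdivide:
                _split_section(m, sid)
    return m


def _split_section(m, sid):
    sec = m.sections[sid]
    half = sec.length / 2
    top = replace(sec, id=sid + "b", parent=sid, length=half, parent_arc=None)
    m.sections[sid] = replace(sec, length=half)
    for child in list(m.sections.values()):
        if child.parent == sid and child.id != top.id:
            arc = child.parent_arc
            if arc is None or arc > half:
                m.sections[child.id] = replace(
                    child, parent=top.id,
                    parent_arc=None if arc is None else arc - half)
    m.sections[top.id] = top


@pytest.mark.parametrize("seed", range(8))
def test_segment_count_matches_chain_oracle(seed):
    rng = np.random.default_rng(seed)
    m = random_tree_morph(rng, n_extra=int(rng.integers(1, 25)))
    assert count_segments(m, "all") == segment_count_oracle(m, "all")


@pytest.mark.parametrize("k", [0, 1, 2, 5, 10])
def test_binary_tree_segment_formula(k):
    """A single stem with k bifurcations carries 2k + 1 segments."""
    rng = np.random.default_rng(k)
    secs = {"soma": make_soma(),
            "s0": SectionNode("s0", DENDRITE, "soma", 20.0, 1.5, 1.5)}
    tips = ["s0"]
    nid = 1
    for _ in range(k):
        t = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            sid = f"s{nid}"
            secs[sid] = SectionNode(sid, DENDRITE, t, 10.0, 1.0, 1.0)
            tips.append(sid)
            nid += 1
    m = NeuronMorphology(secs, 1000.0)
    assert count_segments(m) == 2 * k + 1
    assert segment_count_oracle(m) == 2 * k + 1


def test_unbranched_and_single_bifurcation(toy_neuron):
    assert count_segments(toy_neuron) == 2  # two unbranched primaries
    secs = dict(toy_neuron.sections)
    for sid in ("c1", "c2"):
        secs[sid] = SectionNode(sid, DENDRITE, "d1", 40.0, 1.0, 1.0)
    m = NeuronMorphology(secs, toy_neuron.soma_volume)
    assert count_segments(m) == 4  # d1 stem + two daughters + d2


def test_subdivision_invariance():
    """Splitting any section into two collinear halves changes no summary
    field."""
    rng = np.random.default_rng(5)
    m = random_tree_morph(rng, n_extra=12)
    base = summarize(m).as_dict()
    m2 = random_tree_morph(np.random.default_rng(5), n_extra=12, subdivide=1.0)
    after = summarize(m2).as_dict()
    for key, v in base.items():
        w = after[key]
        if isinstance(v, float) and math.isnan(v):
            assert math.isnan(w)
        else:
            assert w == pytest.approx(v, abs=1e-9), key


def test_identify_abd_and_summary(toy_neuron):
    assert identify_abd(toy_neuron) == "d1"
    s = summarize(toy_neuron)
    assert s.len_total == pytest.approx(200.0)
    assert s.axon_soma_distance == pytest.approx(30.0)
    assert s.axon_start_length == pytest.approx(10.0)
    assert s.ais_soma_distance == pytest.approx(40.0)
    assert s.ais_length == pytest.approx(25.0)
    assert not s.has_somatic_axon


def test_somatic_axon_summary(somatic_axon_neuron):
    assert identify_abd(somatic_axon_neuron) is None
    s = summarize(somatic_axon_neuron)
    assert s.has_somatic_axon
    assert math.isnan(s.len_abd) and math.isnan(s.n_segments_abd)
    assert s.axon_soma_distance == 0.0
    assert s.ais_soma_distance == pytest.approx(s.axon_start_length)
    with pytest.raises(UndefinedMetric):
        count_segments(somatic_axon_neuron, "abd")


def test_additive_identities_on_samples():
    rng = np.random.default_rng(0)
    for stage in ("P3", "P21"):
        p = default_stage_params(stage)
        for _ in range(10):
            s = summarize(sample_neuron(p, rng))
            assert s.len_nabd_avg == pytest.approx(
                s.len_nabd_total / s.n_primary_nabd)
            if not s.has_somatic_axon:
                assert s.len_total == pytest.approx(s.len_abd + s.len_nabd_total)
                assert s.n_segments_total == s.n_segments_abd + s.n_segments_nabd
                assert s.ais_soma_distance == pytest.approx(
                    s.axon_soma_distance + s.axon_start_length)


# ---------------------------------------------------------------------------
# equivalent cylinder and tapering
# ---------------------------------------------------------------------------

def test_equivalent_cylinder_closed_form():
    d, length = equivalent_cylinder(math.pi / 4.0)
    assert d == pytest.approx(1.0)
    assert length == pytest.approx(d)


def test_equivalent_cylinder_p21_mean_volume():
    d, _ = equivalent_cylinder(2489.0)
    assert d == pytest.approx(14.69, abs=0.01)


@given(st.floats(min_value=1.0, max_value=1e5))
def test_equivalent_cylinder_volume_roundtrip(volume):
    d, length = equivalent_cylinder(volume)
    assert math.pi / 4 * d * d * length == pytest.approx(volume, rel=1e-9)


def test_equivalent_cylinder_rejects_nonpositive():
    with pytest.raises(ValueError):
        equivalent_cylinder(0.0)


def test_taper_midpoint_and_tips():
    secs = {"soma": make_soma(),
            "stem": SectionNode("stem", DENDRITE, "soma", 50.0, 2.0, 2.0),
            "c1": SectionNode("c1", DENDRITE, "stem", 50.0, 2.0, 2.0),
            "c2": SectionNode("c2", DENDRITE, "stem", 100.0, 2.0, 2.0)}
    m = NeuronMorphology(secs, 1000.0)
    t = apply_taper(m, terminal_diam=0.5)
    # stem untouched
    assert t.sections["stem"].diam_proximal == 2.0
    assert t.sections["stem"].diam_distal == 2.0
    # terminal sections end exactly at the terminal diameter
    assert t.sections["c1"].diam_distal == pytest.approx(0.5)
    assert t.sections["c2"].diam_distal == pytest.approx(0.5)
    # midpoint of the longest path: half-way from 2.0 to 0.5
    frac = 50.0 / 100.0
    expect = 2.0 + (0.5 - 2.0) * frac
    assert t.sections["c2"].diam_proximal == pytest.approx(2.0)
    mid = 0.5 * (t.sections["c2"].diam_proximal + t.sections["c2"].diam_distal)
    assert mid == pytest.approx(expect)


def test_taper_single_section_dendrite_untouched():
    secs = {"soma": make_soma(),
            "d": SectionNode("d", DENDRITE, "soma", 80.0, 1.8, 1.8)}
    t = apply_taper(NeuronMorphology(secs, 500.0))
    assert t.sections["d"].diam_proximal == 1.8
    assert t.sections["d"].diam_distal == 1.8


def test_taper_rejects_bad_terminal(toy_neuron):
    with pytest.raises(ValueError):
        apply_taper(toy_neuron, terminal_diam=-1.0)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def test_swc_three_point_roundtrip(tmp_path):
    p = tmp_path / "mini.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 50 0 0 1 1\n3 3 100 0 0 1 2\n")
    m = load_morphology(p)
    dend = m.dendrite_sections()
    assert len(dend) == 1
    assert dend[0].length == pytest.approx(100.0)


def test_swc_missing_parent_is_structure_error(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 9\n")
    with pytest.raises(MorphologyError, match="missing parent"):
        load_morphology(p)


def test_swc_malformed_line_names_line(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\nnot a row\n")
    with pytest.raises(MorphologyError, match=":2"):
        load_morphology(p)


def test_swc_roundtrip_preserves_summary(tmp_path, p21_neuron):
    path = tmp_path / "n.swc"
    save_morphology(p21_neuron, path)
    m2 = load_morphology(path)
    a = summarize(p21_neuron).as_dict()
    b = summarize(m2).as_dict()
    for key, v in a.items():
        w = b[key]
        if isinstance(v, float) and math.isnan(v):
            assert math.isnan(w)
        else:
            assert w == pytest.approx(v, abs=1e-5), key


def test_swc_axon_needs_partition_metadata(tmp_path):
    p = tmp_path / "ax.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 2 30 0 0 0.35 1\n")
    with pytest.raises(MorphologyError, match="extents"):
        load_morphology(p)
    m = load_morphology(p, axon_start_length=10.0, ais_length=15.0)
    s = summarize(m)
    assert s.axon_start_length == pytest.approx(10.0)
    assert s.ais_length == pytest.approx(15.0)
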
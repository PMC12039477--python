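"""Branched neuron morphologies and dendritic morphometry.

A morphology is a rooted tree of frustum-shaped sections.  The root is the
soma (represented for simulation purposes by an equivalent cylinder of
matched volume); dendrites branch from the soma; the axonal path leaves the
somatodendritic tree either from the soma or from one dendrite — the
axon-bearing dendrite (ABD) — and runs axon-start -> AIS -> distal axon.

All positions are continuous arc lengths in micrometres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SectionNode",
    "NeuronMorphology",
    "MorphometricSummary",
    "MorphologyError",
    "UndefinedMetric",
    "load_morphology",
    "save_morphology",
    "identify_abd",
    "count_segments",
    "summarize",
    "equivalent_cylinder",
    "apply_taper",
]

SOMA = "soma"
DENDRITE = "dendrite"
AXON_START = "axon_start"
AIS = "ais"
AXON = "axon"

LABELS = (SOMA, DENDRITE, AXON_START, AIS, AXON)
AXONAL = (AXON_START, AIS, AXON)


class MorphologyError(ValueError):
    """Structural or parse problem in a morphology."""


class UndefinedMetric(ValueError):
    """A metric that is undefined for this neuron (e.g. ABD metrics on a
    somatic-axon neuron) was requested as a hard value."""


@dataclass(frozen=True)
class SectionNode:
    """One unbranched cable section.

    ``parent_arc`` is the arc position (µm from the proximal end of the
    parent) at which this section attaches; by convention sections attach at
    the distal end of their parent except the axon_start, which may attach
    anywhere along the soma or a dendritic section.
    """

    id: str
    label: str
    parent: str | None
    length: float
    diam_proximal: float
    diam_distal: float
    parent_arc: float | None = None  # None = distal end of parent

    def __post_init__(self):
        if self.label not in LABELS:
            raise MorphologyError(f"unknown section label {self.label!r}")
        if not (self.length > 0 and self.diam_proximal > 0 and self.diam_distal > 0):
            raise MorphologyError(
                f"section {self.id}: length and diameters must be positive"
            )

    @property
    def diam_mean(self) -> float:
        return 0.5 * (self.diam_proximal + self.diam_distal)

    @property
    def area(self) -> float:
        """Lateral membrane area in µm² (cylindrical approximation)."""
        return math.pi * self.diam_mean * self.length


@dataclass
class NeuronMorphology:
    """Rooted tree of sections with soma volume and axon origin."""

    sections: dict[str, SectionNode]
    soma_volume: float
    name: str = "neuron"
    meta: dict = field(default_factory=dict)

    # -- structure helpers -------------------------------------------------
    def children(self, sid: str) -> list[SectionNode]:
        return [s for s in self.sections.values() if s.parent == sid]

    @property
    def soma(self) -> SectionNode:
        return next(s for s in self.sections.values() if s.label == SOMA)

    @property
    def has_axon(self) -> bool:
        return any(s.label == AXON_START for s in self.sections.values())

    @property
    def axon_start(self) -> SectionNode:
        return next(s for s in self.sections.values() if s.label == AXON_START)

    @property
    def axon_origin(self) -> tuple[str, float]:
        """(section id, arc µm) where the axonal path leaves the tree."""
        ax = self.axon_start
        parent = self.sections[ax.parent]
        arc = ax.parent_arc if ax.parent_arc is not None else parent.length
        return parent.id, arc

    @property
    def has_somatic_axon(self) -> bool:
        return self.has_axon and self.sections[self.axon_start.parent].label == SOMA

    def dendrite_sections(self) -> list[SectionNode]:
        return [s for s in self.sections.values() if s.label == DENDRITE]

    def primary_dendrites(self) -> list[SectionNode]:
        soma_id = self.soma.id
        return [s for s in self.dendrite_sections() if s.parent == soma_id]

    def subtree(self, sid: str) -> list[str]:
        """Ids of sid and all descendants (dendritic descent only stops
        nowhere: axonal children are included)."""
        out, stack = [], [sid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(c.id for c in self.children(cur))
        return out

    def path_to_soma(self, sid: str) -> list[str]:
        path = [sid]
        while self.sections[path[-1]].parent is not None:
            path.append(self.sections[path[-1]].parent)
        return path

    def validate(self) -> None:
        roots = [s for s in self.sections.values() if s.parent is None]
        if len(roots) != 1 or roots[0].label != SOMA:
            raise MorphologyError("morphology must have exactly one root, the soma")
        if sum(s.label == SOMA for s in self.sections.values()) != 1:
            raise MorphologyError("exactly one soma section expected")
        if self.soma_volume <= 0:
            raise MorphologyError("soma volume must be positive")
        # connectivity + acyclicity via reachability from root
        seen = set(self.subtree(roots[0].id))
        if seen != set(self.sections):
            missing = set(self.sections) - seen
            raise MorphologyError(f"disconnected sections: {sorted(missing)}")
        for s in self.sections.values():
            if s.parent is not None and s.parent not in self.sections:
                raise MorphologyError(f"section {s.id} references missing parent {s.parent}")
            if s.parent_arc is not None:
                plen = self.sections[s.parent].length
                if not (0.0 <= s.parent_arc <= plen + 1e-9):
                    raise MorphologyError(
                        f"section {s.id}: parent_arc {s.parent_arc} outside parent length {plen}"
                    )
        # axonal path: contiguous axon_start -> ais -> axon
        starts = [s for s in self.sections.values() if s.label == AXON_START]
        if len(starts) > 1:
            raise MorphologyError("more than one axonal path")
        if starts:
            st = starts[0]
            par = self.sections[st.parent]
            if par.label not in (SOMA, DENDRITE):
                raise MorphologyError("axon_start must attach to soma or a dendrite")
            order = {AXON_START: AIS, AIS: AXON, AXON: AXON}
            for s in self.sections.values():
                if s.label in (AIS, AXON):
                    par = self.sections[s.parent]
                    if par.label not in AXONAL or order[par.label] not in (s.label,):
                        if par.label != s.label:  # chains of same label allowed
                            raise MorphologyError(
                                f"axonal labels out of order at section {s.id}"
                            )
        for lbl in (AIS, AXON):
            if any(s.label == lbl for s in self.sections.values()) and not starts:
                raise MorphologyError(f"{lbl} present without axon_start")


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

@dataclass
class MorphometricSummary:
    """Per-neuron metric vector (NaN marks undefined ABD metrics on
    somatic-axon neurons)."""

    n_segments_total: float
    n_segments_abd: float
    n_segments_nabd: float
    n_primary_nabd: float
    avg_segments_per_nabd: float
    len_total: float
    len_abd: float
    len_nabd_total: float
    len_nabd_avg: float
    axon_soma_distance: float
    axon_start_length: float
    ais_soma_distance: float
    ais_length: float
    soma_volume: float
    has_somatic_axon: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def identify_abd(m: NeuronMorphology) -> str | None:
    """Primary dendrite whose subtree carries the axon origin, or None for a
    somatic axon."""
    if not m.has_axon or m.has_somatic_axon:
        return None
    sid, _ = m.axon_origin
    path = m.path_to_soma(sid)
    soma_id = m.soma.id
    for i, p in enumerate(path):
        if p == soma_id:
            return path[i - 1]
    raise MorphologyError("axon origin not connected to soma")  # pragma: no cover


def _dendritic_children(m: NeuronMorphology, sid: str) -> list[SectionNode]:
    return [c for c in m.children(sid) if c.label == DENDRITE]


def _starts_segment(m: NeuronMorphology, s: SectionNode) -> bool:
    """A dendritic section starts a new topological segment iff its parent is
    the soma or its parent carries >= 2 dendritic children (a branch point).
    The axon leaving a dendrite does not split a dendritic segment."""
    parent = m.sections[s.parent]
    if parent.label == SOMA:
        return True
    return len(_dendritic_children(m, parent.id)) >= 2


def count_segments(m: NeuronMorphology, subset: str = "all") -> int:
    """Number of dendritic segments (branch-point-to-branch-point or
    branch-point-to-tip paths); subset one of {'all','abd','nabd'}."""
    if subset not in ("all", "abd", "nabd"):
        raise ValueError(f"unknown subset {subset!r}")
    abd = identify_abd(m)
    if subset == "abd" and abd is None:
        raise UndefinedMetric("ABD segment count undefined for a somatic-axon neuron")
    abd_ids = set(m.subtree(abd)) if abd is not None else set()
    n = 0
    for s in m.dendrite_sections():
        in_abd = s.id in abd_ids
        if subset == "abd" and not in_abd:
            continue
        if subset == "nabd" and in_abd:
            continue
        if _starts_segment(m, s):
            n += 1
    return n


def summarize(m: NeuronMorphology) -> MorphometricSummary:
    """Compute the full morphometric vector for one neuron."""
    m.validate()
    abd = identify_abd(m)
    somatic = m.has_axon and m.has_somatic_axon
    abd_ids = set(m.subtree(abd)) if abd is not None else set()

    len_total = sum(s.length for s in m.dendrite_sections())
    len_abd = sum(s.length for s in m.dendrite_sections() if s.id in abd_ids)
    len_nabd = len_total - len_abd

    n_total = count_segments(m, "all")
    n_nabd = count_segments(m, "nabd")
    n_abd = n_total - n_nabd

    primaries = m.primary_dendrites()
    n_primary_nabd = sum(1 for p in primaries if p.id != abd)

    if m.has_axon:
        origin_sid, origin_arc = m.axon_origin
        if somatic:
            axon_soma = 0.0
        else:
            path = m.path_to_soma(origin_sid)
            # lengths of full sections between origin's section and the soma
            axon_soma = origin_arc + sum(
                m.sections[p].length for p in path[1:] if m.sections[p].label == DENDRITE
            )
        axon_start_len = sum(s.length for s in m.sections.values() if s.label == AXON_START)
        ais_len = sum(s.length for s in m.sections.values() if s.label == AIS)
        ais_soma = axon_soma + axon_start_len
    else:
        axon_soma = axon_start_len = ais_len = ais_soma = math.nan

    nan = math.nan
    return MorphometricSummary(
        n_segments_total=n_total,
        n_segments_abd=nan if somatic else n_abd,
        n_segments_nabd=n_nabd,
        n_primary_nabd=n_primary_nabd,
        avg_segments_per_nabd=n_nabd / n_primary_nabd if n_primary_nabd else nan,
        len_total=len_total,
        len_abd=nan if somatic else len_abd,
        len_nabd_total=len_nabd,
        len_nabd_avg=len_nabd / n_primary_nabd if n_primary_nabd else nan,
        axon_soma_distance=axon_soma,
        axon_start_length=axon_start_len,
        ais_soma_distance=ais_soma,
        ais_length=ais_len,
        soma_volume=m.soma_volume,
        has_somatic_axon=bool(somatic),
    )


def equivalent_cylinder(volume: float) -> tuple[float, float]:
    """Cylinder with length = diameter and pi d^3 / 4 = volume.

    Returns (diameter, length) in µm for a soma volume in µm³.
    """
    if volume <= 0:
        raise ValueError("soma volume must be positive")
    d = (4.0 * volume / math.pi) ** (1.0 / 3.0)
    return d, d


def apply_taper(
    m: NeuronMorphology,
    terminal_diam: float = 0.5,
    axon_diam: float = 0.7,
) -> NeuronMorphology:
    """Taper non-primary dendrites linearly to ``terminal_diam`` at the tips.

    Primary stems keep their (uniform) primary diameter.  Beyond the first
    branch point, diameter interpolates linearly along path distance from the
    primary-stem diameter down to ``terminal_diam`` reached exactly at the
    most distal tip passing through each section.  Axonal sections are set to
    the constant ``axon_diam``.
    """
    if terminal_diam <= 0:
        raise ValueError("terminal diameter must be positive")
    new = dict(m.sections)

    for prim in m.primary_dendrites():
        d0 = prim.diam_proximal
        # arc distance from the end of the primary stem to each section start
        start: dict[str, float] = {}
        reach: dict[str, float] = {}  # max distance to a downstream tip

        def _walk(sid: str, x0: float) -> float:
            sec = m.sections[sid]
            start[sid] = x0
            kids = _dendritic_children(m, sid)
            x1 = x0 + sec.length
            far = x1 if not kids else max(_walk(k.id, x1) for k in kids)
            reach[sid] = far
            return far

        _walk(prim.id, -prim.length)  # stem occupies x in [-L, 0]
        for sid in start:
            sec = m.sections[sid]
            if sid == prim.id:
                new[sid] = replace(sec, diam_proximal=d0, diam_distal=d0)
                continue
            far = max(reach[sid], 1e-12)
            lo = max(start[sid], 0.0) / far
            hi = (start[sid] + sec.length) / far
            dp = d0 + (terminal_diam - d0) * lo
            dd = d0 + (terminal_diam - d0) * hi
            new[sid] = replace(sec, diam_proximal=dp, diam_distal=dd)

    for sid, sec in list(new.items()):
        if sec.label in AXONAL:
            new[sid] = replace(sec, diam_proximal=axon_diam, diam_distal=axon_diam)

    return NeuronMorphology(new, m.soma_volume, name=m.name, meta=dict(m.meta))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_TYPES = {SOMA: 1, AXON_START: 2, AIS: 2, AXON: 2, DENDRITE: 3}


def save_morphology(m: NeuronMorphology, path: str | Path) -> None:
    """Write standard 7-column SWC plus a side-car ``<path>.json`` carrying
    soma volume and the axon_start/AIS extents (SWC has no AIS type code)."""
    path = Path(path)
    m.validate()
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    # synthetic morphologies carry no 3D embedding; lay sections out on
    # deterministic straight lines so that arc lengths round-trip exactly
    rng = np.random.default_rng(abs(hash(m.name)) % (2**31))
    dirs: dict[str, np.ndarray] = {}

    def _dir(sid: str) -> np.ndarray:
        if sid not in dirs:
            v = rng.normal(size=3)
            dirs[sid] = v / np.linalg.norm(v)
        return dirs[sid]

    soma = m.soma
    r_soma = (3.0 * m.soma_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    rows.append((1, 1, 0.0, 0.0, 0.0, r_soma, -1))
    next_id = 2
    # (point id, 3D position) of the distal end of each section; soma = pt 1
    tip_point: dict[str, tuple[int, np.ndarray]] = {soma.id: (1, np.zeros(3))}
    # points inserted mid-section (for axon origins): section -> [(arc, id, pos)]
    mid_points: dict[str, list[tuple[float, int, np.ndarray]]] = {}

    def _attach_point(sec: SectionNode) -> tuple[int, np.ndarray]:
        parent = m.sections[sec.parent]
        pid, ppos = tip_point[parent.id]
        if sec.parent_arc is None or parent.label == SOMA:
            return pid, ppos
        arc = sec.parent_arc
        if abs(arc - parent.length) < 1e-9:
            return pid, ppos
        # need (or reuse) a sample at this arc along the parent
        for a, mid, mpos in mid_points.get(parent.id, []):
            if abs(a - arc) < 1e-9:
                return mid, mpos
        raise MorphologyError(
            f"no SWC sample at arc {arc} on section {parent.id}"
        )  # pragma: no cover — origins are registered before traversal

    # pre-register mid-section attach arcs (axon origin on a dendrite)
    pending_arcs: dict[str, list[float]] = {}
    for sec in m.sections.values():
        if sec.parent_arc is not None:
            parent = m.sections[sec.parent]
            if parent.label == DENDRITE and abs(sec.parent_arc - parent.length) > 1e-9:
                pending_arcs.setdefault(parent.id, []).append(sec.parent_arc)

    def _emit(sec: SectionNode) -> None:
        nonlocal next_id
        pid, ppos = _attach_point(sec)
        u = _dir(sec.id)
        stype = _SWC_TYPES[sec.label]
        arcs = sorted(set(pending_arcs.get(sec.id, [])))
        prev_arc, prev_id, prev_pos = 0.0, pid, ppos
        for arc in arcs + [sec.length]:
            if arc <= prev_arc + 1e-12:
                continue
            pos = prev_pos + u * (arc - prev_arc)
            frac = arc / sec.length
            radius = 0.5 * (
                sec.diam_proximal + frac * (sec.diam_distal - sec.diam_proximal)
            )
            rows.append((next_id, stype, *pos, radius, prev_id))
            if arc < sec.length - 1e-12:
                mid_points.setdefault(sec.id, []).append((arc, next_id, pos))
            else:
                tip_point[sec.id] = (next_id, pos)
            prev_arc, prev_id, prev_pos = arc, next_id, pos
            next_id += 1
        for child in m.children(sec.id):
            _emit(child)

    for child in m.children(soma.id):
        _emit(child)

    with open(path, "w") as fh:
        fh.write("# SWC export\n")
        for i, t, x, y, z, r, p in rows:
            fh.write(f"{i} {t} {x:.9g} {y:.9g} {z:.9g} {r:.9g} {p}\n")
    axon_start_len = sum(s.length for s in m.sections.values() if s.label == AXON_START)
    ais_len = sum(s.length for s in m.sections.values() if s.label == AIS)
    meta = {
        "soma_volume": m.soma_volume,
        "axon_start_length": axon_start_len if m.has_axon else None,
        "ais_length": ais_len if m.has_axon else None,
        "name": m.name,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_morphology(
    path: str | Path,
    axon_start_length: float | None = None,
    ais_length: float | None = None,
    soma_volume: float | None = None,
) -> NeuronMorphology:
    """Load a standard 7-column SWC file.

    The axon_start/AIS/axon partition of the axonal path is not expressible
    in SWC type codes; it is read from a side-car ``<path>.json`` when
    present, else from the keyword arguments.  Soma volume defaults to the
    volume of the soma samples (sphere for a single sample).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = Path(str(path) + ".json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if axon_start_length is None:
        axon_start_length = meta.get("axon_start_length")
    if ais_length is None:
        ais_length = meta.get("ais_length")
    if soma_volume is None:
        soma_volume = meta.get("soma_volume")

    ids: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
        try:
            i, t, p = int(parts[0]), int(parts[1]), int(parts[6])
            x, y, z, r = map(float, parts[2:6])
        except ValueError as e:
            raise MorphologyError(f"{path}:{ln}: {e}") from None
        if i in ids:
            raise MorphologyError(f"{path}:{ln}: duplicate point id {i}")
        ids[i] = (t, np.array([x, y, z]), r, p)
    if not ids:
        raise MorphologyError(f"{path}: empty SWC file")
    for i, (t, pos, r, p) in ids.items():
        if p != -1 and p not in ids:
            raise MorphologyError(f"{path}: point {i} references missing parent {p}")
    roots = [i for i, v in ids.items() if v[3] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"{path}: expected one root point, found {len(roots)}")
    root = roots[0]
    if ids[root][0] != 1:
        raise MorphologyError(f"{path}: root point must be soma (type 1)")

    children: dict[int, list[int]] = {i: [] for i in ids}
    for i, (_, _, _, p) in ids.items():
        if p != -1:
            children[p].append(i)

    soma_pts = [i for i, v in ids.items() if v[0] == 1]
    if soma_volume is None:
        if len(soma_pts) == 1:
            r = ids[soma_pts[0]][2]
            soma_volume = 4.0 / 3.0 * math.pi * r**3
        else:  # chain of frusta
            soma_volume = 0.0
            for i in soma_pts:
                t, pos, r, p = ids[i]
                if p in soma_pts:
                    _, ppos, pr, _ = ids[p]
                    h = float(np.linalg.norm(pos - ppos))
                    soma_volume += math.pi * h / 3.0 * (r * r + r * pr + pr * pr)
            if soma_volume <= 0:
                r = max(ids[i][2] for i in soma_pts)
                soma_volume = 4.0 / 3.0 * math.pi * r**3

    # build unbranched point runs (sections) over non-soma points
    soma_set = set(soma_pts)
    d_soma, l_soma = equivalent_cylinder(soma_volume)
    sections: dict[str, SectionNode] = {
        "soma": SectionNode("soma", SOMA, None, l_soma, d_soma, d_soma)
    }
    counter = [0]

    def _new_id(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    def _grow(start_pt: int, parent_sid: str) -> None:
        """Consume an unbranched run starting at start_pt into one section."""
        t0 = ids[start_pt][0]
        pts = [start_pt]
        while True:
            kids = [k for k in children[pts[-1]] if k not in soma_set]
            if len(kids) == 1 and ids[kids[0]][0] == t0:
                pts.append(kids[0])
            else:
                break
        p_first = ids[pts[0]][3]
        prev_pos = ids[p_first][1] if p_first != -1 else ids[pts[0]][1]
        length = 0.0
        for q in pts:
            length += float(np.linalg.norm(ids[q][1] - prev_pos))
            prev_pos = ids[q][1]
        if length <= 0:
            length = 1e-6
        r0 = ids[p_first][2] if p_first not in soma_set and p_first != -1 else ids[pts[0]][2]
        r1 = ids[pts[-1]][2]
        label = DENDRITE if t0 in (3, 4) else (AXON if t0 == 2 else DENDRITE)
        sid = _new_id("d" if label == DENDRITE else "ax")
        sections[sid] = SectionNode(
            sid, label, parent_sid, length, max(2 * r0, 1e-6), max(2 * r1, 1e-6)
        )
        for k in [k for k in children[pts[-1]] if k not in soma_set]:
            _grow(k, sid)

    for i in soma_pts:
        for k in children[i]:
            if k not in soma_set:
                _grow(k, "soma")

    m = NeuronMorphology(sections, soma_volume, name=path.stem, meta=meta)
    _partition_axon(m, axon_start_length, ais_length)
    m.validate()
    return m


def _partition_axon(
    m: NeuronMorphology, axon_start_length: float | None, ais_length: float | None
) -> None:
    """Relabel the raw AXON run(s) into axon_start / ais / axon by arc
    distance from the axon origin."""
    raw = [s for s in m.sections.values() if s.label in AXONAL]
    if not raw:
        return
    if axon_start_length is None or ais_length is None:
        raise MorphologyError(
            "SWC has an axon but no axon_start/AIS extents: supply them via "
            "the side-car JSON or keyword arguments"
        )
    # walk the (assumed unbranched) axonal path from its origin
    raw_ids = {s.id for s in raw}
    heads = [s for s in raw if s.parent not in raw_ids]
    if len(heads) != 1:
        raise MorphologyError("expected a single axonal path")
    order = []
    cur = heads[0]
    while True:
        order.append(cur)
        nxt = [c for c in m.children(cur.id) if c.id in raw_ids]
        if not nxt:
            break
        if len(nxt) > 1:
            raise MorphologyError("branched axonal path not supported")
        cur = nxt[0]
    b1, b2 = axon_start_length, axon_start_length + ais_length
    pos = 0.0
    new_secs: list[SectionNode] = []
    parent_sid = heads[0].parent
    parent_arc = heads[0].parent_arc
    counter = 0
    for sec in order:
        cuts = [c - pos for c in (b1, b2) if pos + 1e-9 < c < pos + sec.length - 1e-9]
        edges = [0.0] + cuts + [sec.length]
        for a, b in zip(edges[:-1], edges[1:]):
            mid = pos + 0.5 * (a + b)
            label = AXON_START if mid < b1 else (AIS if mid < b2 else AXON)
            counter += 1
            sid = f"axp{counter}"
            frac_a, frac_b = a / sec.length, b / sec.length
            dp = sec.diam_proximal + frac_a * (sec.diam_distal - sec.diam_proximal)
            dd = sec.diam_proximal + frac_b * (sec.diam_distal - sec.diam_proximal)
            new_secs.append(
                SectionNode(sid, label, parent_sid, b - a, dp, dd, parent_arc)
            )
            parent_sid, parent_arc = sid, None
        pos += sec.length
    for sec in order:
        del m.sections[sec.id]
    for sec in new_secs:
        m.sections[sec.id] = sec
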
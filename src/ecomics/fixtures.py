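"""Seeded synthetic-data generators for every tool in the suite.

These generators emulate the shapes of the study designs the tools were
built around — microcosm NMR time series, lignocellulose HSQC peak
lists, small-n multi-omics matrices with planted correlated pairs, and
all-vs-all similarity hit tables — without requiring any download. Every
generator is fully deterministic under its ``seed`` (one private
``numpy`` Generator per call, no global state) and emits objects that
serialize through :mod:`ecomics.io_formats` without special-casing.

They model convenient idealizations, not instrument physics: NMR lines
are Gaussian (no Lorentzian tails, J-coupling or phase error), planted
correlations are a shared latent factor plus i.i.d. Gaussian noise, and
similarity graphs have clean module boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bmchar import (
    ALIPHATIC_CATEGORIES,
    AROMATIC_CATEGORIES,
    HEMICELLULOSE_CATEGORIES,
    PeakList,
    RoiDatabase,
    RoiEntry,
)
from .eclass import ModuleSet
from .io_formats import HitRecord, HitTable, SampleMatrix, SpectrumGrid, TaxonomyTable

__all__ = [
    "AxisSpec",
    "gen_spectrum",
    "gen_peaklist",
    "gen_correlated_matrices",
    "gen_similarity_graph",
    "gen_hit_table",
    "gen_roi_database",
]


@dataclass(frozen=True)
class AxisSpec:
    """A regular ppm axis: n_points spanning [ppm_min, ppm_max]."""

    ppm_min: float
    ppm_max: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")

    def values(self) -> np.ndarray:
        """The axis, downfield (high ppm) first."""
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


def gen_spectrum(
    peaks: list[tuple],
    axis: AxisSpec,
    axis_f2: AxisSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> SpectrumGrid:
    """Sum of Gaussian lines on a regular ppm grid plus seeded noise.

    1D peaks are ``(ppm, amplitude, width)``; with ``axis_f2`` given the
    spectrum is 2D and peaks are ``((f1_ppm, f2_ppm), amplitude,
    (f1_width, f2_width))``. A peak center outside its axis raises a
    warning and contributes only its in-range tail.
    """
    rng = np.random.default_rng(seed)
    if axis_f2 is None:
        x = axis.values()
        grid = np.zeros_like(x)
        for pos, amp, width in peaks:
            if width <= 0:
                raise ValueError("peak widths must be positive")
            if not axis.ppm_min <= pos <= axis.ppm_max:
                warnings.warn(f"peak at {pos} ppm lies outside the axis", stacklevel=2)
            grid += amp * _gauss(x, pos, width)
        if noise_sd > 0:
            grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
        return SpectrumGrid([x], grid, label=label)

    f1, f2 = axis.values(), axis_f2.values()
    grid2 = np.zeros((f1.size, f2.size))
    for (p1, p2), amp, (w1, w2) in peaks:
        if w1 <= 0 or w2 <= 0:
            raise ValueError("peak widths must be positive")
        if not (axis.ppm_min <= p1 <= axis.ppm_max and axis_f2.ppm_min <= p2 <= axis_f2.ppm_max):
            warnings.warn(f"peak at ({p1}, {p2}) ppm lies outside the axes", stacklevel=2)
        grid2 += amp * np.outer(_gauss(f1, p1, w1), _gauss(f2, p2, w2))
    if noise_sd > 0:
        grid2 = grid2 + rng.normal(0.0, noise_sd, size=grid2.shape)
    return SpectrumGrid([f1, f2], grid2, label=label)


def gen_peaklist(
    db: RoiDatabase,
    picks: list[str] | int,
    jitter_h: float = 0.0,
    jitter_c: float = 0.0,
    intensity_range: tuple[float, float] | None = (1.0, 10.0),
    seed: int = 0,
) -> tuple[PeakList, list[str]]:
    """Peaks at chosen ROI centers plus uniform jitter, with ground truth.

    ``picks`` is either a list of entry ids or a count of entries drawn
    without replacement. Returns ``(peaks, truth)`` where ``truth[i]``
    is the generating entry id of peak i.
    """
    if jitter_h < 0 or jitter_c < 0:
        raise ValueError("jitters must be nonnegative")
    rng = np.random.default_rng(seed)
    ids = {e.id: e for e in db.entries}
    if isinstance(picks, int):
        if picks > len(ids):
            raise ValueError(f"cannot pick {picks} distinct entries from {len(ids)}")
        chosen = list(rng.choice(sorted(ids), size=picks, replace=False))
    else:
        missing = [p for p in picks if p not in ids]
        if missing:
            raise ValueError(f"pick ids absent from database: {missing}")
        chosen = list(picks)
    h = np.array([ids[c].h_center for c in chosen])
    c = np.array([ids[c].c_center for c in chosen])
    if jitter_h > 0:
        h = h + rng.uniform(-jitter_h, jitter_h, size=h.shape)
    if jitter_c > 0:
        c = c + rng.uniform(-jitter_c, jitter_c, size=c.shape)
    inten = None
    if intensity_range is not None:
        lo, hi = intensity_range
        inten = rng.uniform(lo, hi, size=h.shape)
    return PeakList(h, c, inten), chosen


def gen_correlated_matrices(
    blocks: list[tuple[str, int]],
    planted_pairs: list[tuple[str, str, int]],
    n_samples: int = 7,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[list[SampleMatrix], list[tuple[str, str, int]]]:
    """Sample matrices with planted correlated row pairs.

    ``blocks`` lists ``(block_label, n_rows)``; rows are named
    ``<label><index>`` (A1, A2, ...). ``planted_pairs`` lists
    ``(row_a, row_b, sign)`` by those names (sign +1 or -1): the pair
    shares one standard-normal latent factor (negated on the second row
    for sign -1) plus independent ``noise_sd`` Gaussian noise, the
    small-n multi-omics situation where a taxon's abundance tracks a
    metabolite across a handful of time points. Non-planted rows are
    independent standard normals. Returns the matrices and the planted
    truth table.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    row_names: dict[str, tuple[int, int]] = {}
    for b, (label, n_rows) in enumerate(blocks):
        for i in range(n_rows):
            row_names[f"{label}{i + 1}"] = (b, i)
    for a, b_, sign in planted_pairs:
        for name in (a, b_):
            if name not in row_names:
                raise ValueError(f"planted pair references missing row {name!r}")
        if sign not in (1, -1):
            raise ValueError("planted sign must be +1 or -1")

    # union planted rows into latent groups with relative signs
    parent: dict[str, str] = {}
    rel_sign: dict[str, int] = {}

    def find(x: str) -> tuple[str, int]:
        sign = 1
        while parent.get(x, x) != x:
            sign *= rel_sign[x]
            x = parent[x]
        return x, sign

    for a, b_, sign in planted_pairs:
        for name in (a, b_):
            parent.setdefault(name, name)
            rel_sign.setdefault(name, 1)
        ra, sa = find(a)
        rb, sb = find(b_)
        if ra != rb:
            parent[rb] = ra
            rel_sign[rb] = sa * sign * sb

    latents: dict[str, np.ndarray] = {}
    mats: list[SampleMatrix] = []
    for label, n_rows in blocks:
        values = np.empty((n_rows, n_samples))
        ids = [f"{label}{i + 1}" for i in range(n_rows)]
        for i, name in enumerate(ids):
            if name in parent:
                root, sign = find(name)
                if root not in latents:
                    latents[root] = rng.standard_normal(n_samples)
                values[i] = sign * latents[root] + noise_sd * rng.standard_normal(n_samples)
            else:
                values[i] = rng.standard_normal(n_samples)
        mats.append(
            SampleMatrix(
                row_ids=ids,
                sample_labels=[f"S{j + 1}" for j in range(n_samples)],
                values=values,
                block_label=label,
            )
        )
    return mats, list(planted_pairs)


def gen_similarity_graph(
    module_sizes: list[int],
    hub_per_module: bool = True,
    extra_edge_prob: float = 0.0,
    seed: int = 0,
) -> tuple[nx.Graph, ModuleSet]:
    """Disjoint connected modules with known truth partition.

    Each module ``k`` gets nodes ``m{k}n{i}``. With ``hub_per_module``
    the first node is wired to every module member (a strict-maximum-
    degree hub for modules of size >= 3); otherwise the module is
    connected by a random spanning path. ``extra_edge_prob`` adds random
    intra-module edges. The truth ModuleSet names the hub (or the
    lexicographically smallest member) as representative.
    """
    if any(s < 1 for s in module_sizes):
        raise ValueError("module sizes must be >= 1")
    rng = np.random.default_rng(seed)
    g: nx.Graph = nx.Graph()
    modules: list[frozenset[str]] = []
    reps: list[str] = []
    for k, size in enumerate(module_sizes):
        names = [f"m{k + 1}n{i + 1}" for i in range(size)]
        g.add_nodes_from(names)
        hub = names[0]
        if hub_per_module:
            for other in names[1:]:
                g.add_edge(hub, other)
        else:
            order = list(rng.permutation(names))
            for a, b in zip(order, order[1:]):
                g.add_edge(a, b)
        if extra_edge_prob > 0 and size > 2:
            for i in range(1, size):
                for j in range(i + 1, size):
                    if rng.random() < extra_edge_prob:
                        g.add_edge(names[i], names[j])
        modules.append(frozenset(names))
        reps.append(hub if hub_per_module else min(names))
    order_idx = sorted(range(len(reps)), key=lambda i: reps[i])
    truth = ModuleSet([modules[i] for i in order_idx], [reps[i] for i in order_idx])
    return g, truth


def gen_hit_table(
    composition: dict[str, int],
    e_value_range: tuple[float, float] = (1e-120, 1e-60),
    n_decoys: int = 2,
    seed: int = 0,
    rank_kind: str = "phylum",
) -> tuple[HitTable, TaxonomyTable]:
    """Queries whose best hits carry the requested labels, plus decoys.

    ``composition`` maps a label (e.g. a phylum name, or a CBM family
    when ``rank_kind="CBM"``) to the number of queries that should
    classify to it. Each query receives one planted best hit inside
    ``e_value_range`` and ``n_decoys`` decoy hits at strictly worse
    (larger) E-values and lower bit scores, so the planted hit always
    wins under the best-hit tie rules.
    """
    rng = np.random.default_rng(seed)
    lo, hi = e_value_range
    if not 0 < lo <= hi:
        raise ValueError("e_value_range must satisfy 0 < lo <= hi")
    records: list[HitRecord] = []
    taxa = TaxonomyTable()
    decoy_subject = "subj_decoy"
    if rank_kind == "CBM":
        taxa.cbm_families[decoy_subject] = ("CBM0",)
    else:
        taxa.lineages[decoy_subject] = dict(
            zip(
                ("domain", "phylum", "class", "order", "family"),
                ("Bacteria", "Decoyphylum", "unclassified", "unclassified", "unclassified"),
            )
        )
    q = 0
    for label in sorted(composition):
        count = composition[label]
        if count < 0:
            raise ValueError("composition counts must be >= 0")
        subject = f"subj_{label.replace(' ', '_')}"
        if rank_kind == "CBM":
            taxa.cbm_families[subject] = tuple(t.strip() for t in label.split(","))
        else:
            taxa.lineages[subject] = dict(
                zip(
                    ("domain", "phylum", "class", "order", "family"),
                    ("Bacteria", label, "unclassified", "unclassified", "unclassified"),
                )
            )
        for _ in range(count):
            q += 1
            qid = f"query{q:03d}"
            e_best = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            records.append(
                HitRecord(qid, subject, 98.0, 500, e_best, 900.0 + rng.uniform(0, 50))
            )
            for _ in range(n_decoys):
                e_decoy = float(e_best * 10 ** rng.uniform(3, 20))
                records.append(
                    HitRecord(qid, decoy_subject, 80.0, 400, e_decoy, 200.0 + rng.uniform(0, 50))
                )
    return HitTable(records), taxa


# ---------------------------------------------------------------------------
# synthetic ROI reference table
# ---------------------------------------------------------------------------

_CLASS_BOXES = {
    # signal_class: (h_lo, h_hi, c_lo, c_hi) — class-typical HSQC regions
    "lignin-aromatic": (6.0, 8.0, 100.0, 135.0),
    "lignin-aliphatic": (3.0, 6.0, 50.0, 90.0),
    "hemicellulose": (3.0, 5.5, 60.0, 110.0),
    "uncategorized": (0.5, 2.5, 10.0, 40.0),
}
_CLASS_COLORS = {
    "lignin-aromatic": "brown",
    "lignin-aliphatic": "red",
    "hemicellulose": ("green", "blue", "purple"),
    "uncategorized": "grey",
}


def gen_roi_database(
    seed: int = 0,
    class_counts: dict[str, int] | None = None,
    min_separation: float = 3.0,
    tol_h: float = 0.03,
    tol_c: float = 0.53,
) -> RoiDatabase:
    """A synthetic lignocellulose ROI table with the curated class structure.

    Entry centers are drawn uniformly inside class-typical HSQC boxes and
    rejected until every pair is at least ``min_separation`` apart in
    tolerance-normalized distance, so jittered fixture peaks always
    resolve to their generating entry. Default counts reproduce the
    curated database's structure: 42 aromatic-lignin, 17 aliphatic-
    lignin, 26 hemicellulose, 3 uncategorized (88 signals).
    """
    if class_counts is None:
        class_counts = {
            "lignin-aromatic": 42,
            "lignin-aliphatic": 17,
            "hemicellulose": 26,
            "uncategorized": 3,
        }
    rng = np.random.default_rng(seed)
    placed_h: list[float] = []
    placed_c: list[float] = []
    entries: list[RoiEntry] = []

    def place(h_lo: float, h_hi: float, c_lo: float, c_hi: float) -> tuple[float, float]:
        for _ in range(10000):
            h = rng.uniform(h_lo, h_hi)
            c = rng.uniform(c_lo, c_hi)
            ok = all(
                ((h - ph) / tol_h) ** 2 + ((c - pc) / tol_c) ** 2 >= min_separation**2
                for ph, pc in zip(placed_h, placed_c)
            )
            if ok:
                placed_h.append(h)
                placed_c.append(c)
                return h, c
        raise RuntimeError("could not place a sufficiently separated ROI center")

    def categories_for(cls: str) -> tuple[str, ...]:
        return {
            "lignin-aromatic": AROMATIC_CATEGORIES,
            "lignin-aliphatic": ALIPHATIC_CATEGORIES,
            "hemicellulose": HEMICELLULOSE_CATEGORIES,
            "uncategorized": ("Uncategorized",),
        }[cls]

    idx = 0
    for cls in ("lignin-aromatic", "lignin-aliphatic", "hemicellulose", "uncategorized"):
        count = class_counts.get(cls, 0)
        cats = categories_for(cls)
        box = _CLASS_BOXES[cls]
        colors = _CLASS_COLORS[cls]
        for i in range(count):
            idx += 1
            cat = cats[i % len(cats)]
            h, c = place(*box)
            color = colors[i % len(colors)] if isinstance(colors, tuple) else colors
            entries.append(
                RoiEntry(
                    id=f"roi{idx:03d}",
                    h_center=round(h, 4),
                    c_center=round(c, 4),
                    signal_class=cls,
                    detailed_category=cat,
                    color_group=color,
                )
            )
    return RoiDatabase(entries)
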
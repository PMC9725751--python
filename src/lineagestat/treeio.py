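"""Lineage tree input/output and per-lineage statistics extraction.

A *lineage* is the history of one cell present at the end of an observation
window, traced back to its ancestor at the start of the window.  Bifurcations
in a genealogical tree are cell divisions; the number of divisions D along a
lineage is the elementary fitness proxy of the whole framework.

Two acquisition geometries are supported:

``tree`` mode
    Complete genealogies (agar pads, microchamber arrays): the number of
    founder cells N0 and of final cells Nτ are both observed, and the
    dyadic conservation law ``sum(2**-D) == N0`` holds exactly.

``chronological`` mode
    Isolated single-cell lineages (mother machines): each observed lineage is
    a chronological-statistics sample; Nτ is not observed and is estimated as
    ``sum(2**D)``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "TraitSeries",
    "LineageRecord",
    "LineageEnsemble",
    "ConservationError",
    "LostCellError",
    "parse_cell_table",
    "parse_newick",
    "cell_table_to_newick",
    "lineage_trait_timeaverage",
    "attach_timeaveraged_trait",
    "read_cell_table",
    "write_cell_table",
    "read_lineage_table",
    "write_lineage_table",
    "read_trait_series",
]

#: reserved trait name for the division count
DIVISION_TRAIT = "D"

FATES = ("divided", "alive_at_end", "lost")


class LostCellError(ValueError):
    """A lost (censored) cell was encountered in strict mode."""


class ConservationError(ValueError):
    """The dyadic conservation law sum(2**-D) == N0 is violated."""


@dataclass(frozen=True)
class CellRecord:
    """One cell in a genealogical tree.

    ``end_time`` is the division time when ``fate == 'divided'``, otherwise
    the time the cell left observation.  Times are in hours.
    """

    cell_id: str
    parent_id: str | None
    birth_time: float
    end_time: float
    fate: str = "divided"

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}; expected one of {FATES}")
        if self.end_time < self.birth_time:
            raise ValueError(
                f"cell {self.cell_id}: end_time {self.end_time} < birth_time {self.birth_time}"
            )


@dataclass(frozen=True)
class TraitSeries:
    """Sampled trait time course of a single cell.

    samples: ordered (t_i, x(t_i)) pairs; times strictly increasing and
    within the owning cell's lifespan.
    """

    cell_id: str
    trait_name: str
    samples: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"trait series for cell {self.cell_id}: times must strictly increase")


@dataclass(frozen=True)
class LineageRecord:
    """One lineage: its division count and any scalar lineage traits."""

    lineage_id: str
    divisions: int
    traits: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.divisions < 0 or int(self.divisions) != self.divisions:
            raise ValueError(f"lineage {self.lineage_id}: division count must be a non-negative integer")

    def trait_value(self, name: str) -> float:
        if name == DIVISION_TRAIT:
            return float(self.divisions)
        return float(self.traits[name])


@dataclass
class LineageEnsemble:
    """A set of lineages over an observation window [t_start, t_end].

    In tree mode ``n0`` may be fractional only for bootstrap replicates
    (where it is defined as sum(2**-D) and conservation holds by
    construction).
    """

    mode: str  # "tree" | "chronological"
    records: list[LineageRecord]
    n0: float
    t_start: float
    t_end: float
    n_tau: float | None = None  # observed Nτ (tree mode)
    conserved: bool = True
    #: optional lineage_id -> root-to-terminal cell-id path (tree mode)
    paths: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tree", "chronological"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.t_end <= self.t_start:
            raise ValueError("observation window must have t_end > t_start")
        if not self.records:
            raise ValueError("ensemble has no lineages")
        if self.mode == "tree":
            if self.n_tau is None:
                self.n_tau = float(len(self.records))
            if self.n_tau != len(self.records):
                raise ValueError("tree mode requires n_tau == number of lineages")
        else:
            if self.n0 != len(self.records):
                raise ValueError("chronological mode requires n0 == number of lineages")

    # -- basic views ------------------------------------------------------

    @property
    def tau(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_lineages(self) -> int:
        return len(self.records)

    @property
    def divisions(self) -> np.ndarray:
        return np.array([r.divisions for r in self.records], dtype=np.int64)

    @property
    def n_tau_hat(self) -> float:
        """Nτ: observed in tree mode, estimated as sum(2**D) otherwise."""
        if self.mode == "tree":
            return float(self.n_tau)
        return float(np.sum(np.exp2(self.divisions.astype(float))))

    def trait_values(self, name: str) -> np.ndarray:
        if name == DIVISION_TRAIT:
            return self.divisions.astype(float)
        return np.array([r.trait_value(name) for r in self.records], dtype=float)

    @property
    def trait_names(self) -> list[str]:
        names: list[str] = []
        for r in self.records:
            for k in r.traits:
                if k not in names:
                    names.append(k)
        return names

    # -- invariants -------------------------------------------------------

    def check_conservation(self, strict: bool = True) -> bool:
        """Verify sum(2**-D) == N0 in exact dyadic arithmetic (tree mode)."""
        if self.mode != "tree":
            return True
        total = sum(Fraction(1, 2 ** r.divisions) for r in self.records)
        n0 = Fraction(self.n0).limit_denominator(1 << 60) if not float(self.n0).is_integer() else Fraction(int(self.n0))
        ok = total == n0 if float(self.n0).is_integer() else math.isclose(float(total), self.n0, rel_tol=1e-12)
        if not ok and strict:
            raise ConservationError(
                f"sum(2**-D) = {float(total)} != N0 = {self.n0}: incomplete tree"
            )
        return ok

    def subset(self, indices: Sequence[int]) -> "LineageEnsemble":
        """Ensemble restricted to ``indices`` (used for missing-trait drops)."""
        recs = [self.records[i] for i in indices]
        if self.mode == "tree":
            n0 = float(sum(2.0 ** -r.divisions for r in recs))
            return LineageEnsemble("tree", recs, n0, self.t_start, self.t_end,
                                   n_tau=float(len(recs)), conserved=self.conserved)
        return LineageEnsemble("chronological", recs, float(len(recs)),
                               self.t_start, self.t_end)

    def with_traits(self, name: str, values: Sequence[float]) -> "LineageEnsemble":
        """Copy of the ensemble with trait ``name`` set per lineage."""
        if len(values) != len(self.records):
            raise ValueError("one trait value per lineage required")
        recs = [
            LineageRecord(r.lineage_id, r.divisions, {**dict(r.traits), name: float(v)})
            for r, v in zip(self.records, values)
        ]
        return LineageEnsemble(self.mode, recs, self.n0, self.t_start, self.t_end,
                               n_tau=self.n_tau, conserved=self.conserved, paths=self.paths)


# ---------------------------------------------------------------------------
# tree construction from cell tables
# ---------------------------------------------------------------------------

def _alive_at(cell: CellRecord, t: float) -> bool:
    # division at exactly t belongs to the closing window: the daughters,
    # born at t, are the cells present at t (open-at-start convention)
    if cell.birth_time > t:
        return False
    if cell.end_time > t:
        return True
    return cell.end_time == t and cell.fate != "divided"


def parse_cell_table(
    rows: Iterable[CellRecord] | pd.DataFrame,
    t_start: float,
    t_end: float,
    policy: str = "strict",
) -> LineageEnsemble:
    """Build a tree-mode ensemble from cell records over [t_start, t_end].

    Division counting is open at the window start and closed at its end:
    a division at time t contributes iff ``t_start < t <= t_end``.  Cells
    alive at ``t_start`` are the N0 founders; cells alive at ``t_end`` are
    the Nτ lineage terminals.

    policy: 'strict' raises :class:`LostCellError` on lost cells inside the
    window; 'lenient' drops the affected subtrees, emits a warning and flags
    the broken conservation law on the returned ensemble.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError("policy must be 'strict' or 'lenient'")
    if not t_start < t_end:
        raise ValueError("empty observation window: t_start must be < t_end")

    if isinstance(rows, pd.DataFrame):
        rows = [
            CellRecord(
                str(r.cell_id),
                None if pd.isna(r.parent_id) or r.parent_id == "" else str(r.parent_id),
                float(r.birth_time),
                float(r.end_time),
                str(r.fate),
            )
            for r in rows.itertuples(index=False)
        ]
    cells = {c.cell_id: c for c in rows}
    if not cells:
        raise ValueError("no cell records given")
    children: dict[str, list[str]] = {cid: [] for cid in cells}
    for c in cells.values():
        if c.parent_id is not None:
            if c.parent_id not in cells:
                raise ValueError(f"cell {c.cell_id}: unknown parent {c.parent_id}")
            parent = cells[c.parent_id]
            if parent.end_time != c.birth_time:
                raise ValueError(
                    f"cell {c.cell_id}: birth_time {c.birth_time} != parent's end_time {parent.end_time}"
                )
            children[c.parent_id].append(c.cell_id)
    for cid, kids in children.items():
        if cells[cid].fate == "divided" and kids and len(kids) != 2:
            raise ValueError(f"cell {cid} divided into {len(kids)} cells; binary division required")

    lost = [c for c in cells.values()
            if c.fate == "lost" and t_start < c.end_time <= t_end and c.birth_time <= t_end]
    conserved = True
    if lost:
        ids = sorted(c.cell_id for c in lost)
        if policy == "strict":
            raise LostCellError(
                f"lost cells inside the window: {ids}; conservation sum(2**-D) == N0 "
                "cannot hold (use policy='lenient' to drop their subtrees)"
            )
        warnings.warn(
            f"dropping {len(ids)} lost cell(s) {ids}: sum(2**-D) != N0 for this ensemble",
            stacklevel=2,
        )
        conserved = False

    founders = [c.cell_id for c in cells.values() if _alive_at(c, t_start)]
    if not founders:
        raise ValueError(f"no cell is alive at t_start={t_start}")

    records: list[LineageRecord] = []
    paths: dict[str, list[str]] = {}
    # iterative DFS from each founder, counting in-window divisions
    for root in sorted(founders):
        stack: list[tuple[str, int, list[str]]] = [(root, 0, [root])]
        while stack:
            cid, d, path = stack.pop()
            cell = cells[cid]
            if _alive_at(cell, t_end):
                records.append(LineageRecord(cid, d))
                paths[cid] = path
                continue
            if cell.fate == "divided" and cell.end_time <= t_end:
                for kid in sorted(children[cid]):
                    stack.append((kid, d + 1 if cell.end_time > t_start else d, path + [kid]))
            # lost or out-of-window cells terminate silently (lenient) —
            # strict mode raised above

    if not records:
        raise ValueError(f"no cell is alive at t_end={t_end}")
    records.sort(key=lambda r: r.lineage_id)
    ens = LineageEnsemble(
        "tree", records, float(len(founders)), t_start, t_end,
        n_tau=float(len(records)), conserved=conserved, paths=paths,
    )
    ens.check_conservation(strict=conserved)
    return ens


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def parse_newick(text: str, t_end: float, t_start: float | None = None) -> LineageEnsemble:
    """Read a binary lineage tree in Newick form.

    Leaves are the cells alive at ``t_end``; every internal node is one cell
    division, so a leaf's division count is the number of internal nodes on
    its root-to-leaf path.  Branch lengths (hours) fix the window duration:
    ``t_start = t_end - max root-to-leaf distance`` unless given explicitly.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ValueError(f"malformed Newick: {exc}") from exc

    records: list[LineageRecord] = []
    depths: dict = {}
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if n_children not in (0, 2):
            raise ValueError(
                f"non-binary internal node with {n_children} children; lineage trees are binary"
            )
        parent_divs = depths.get(node.parent_node, 0)
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else f"leaf{len(records)}"
            records.append(LineageRecord(label, parent_divs))
        else:
            depths[node] = parent_divs + 1

    if t_start is None:
        dists = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        span = max(dists) if dists else 0.0
        if span <= 0:
            raise ValueError(
                "tree has no branch lengths; pass t_start explicitly to fix the window"
            )
        t_start = t_end - span
    records.sort(key=lambda r: r.lineage_id)
    ens = LineageEnsemble("tree", records, 1.0, t_start, t_end, n_tau=float(len(records)))
    ens.check_conservation()
    return ens


def cell_table_to_newick(rows: Iterable[CellRecord]) -> str:
    """Serialize a single-rooted cell table as a Newick string."""
    cells = {c.cell_id: c for c in rows}
    children: dict[str, list[str]] = {cid: [] for cid in cells}
    roots = []
    for c in cells.values():
        if c.parent_id is None:
            roots.append(c.cell_id)
        else:
            children[c.parent_id].append(c.cell_id)
    if len(roots) != 1:
        raise ValueError(f"Newick export needs exactly one root, found {len(roots)}")

    def render(cid: str) -> str:
        c = cells[cid]
        length = c.end_time - c.birth_time
        kids = sorted(children[cid])
        if not kids:
            return f"{cid}:{length:g}"
        return f"({','.join(render(k) for k in kids)}):{length:g}"

    return render(roots[0]) + ";"


# ---------------------------------------------------------------------------
# trait time series
# ---------------------------------------------------------------------------

def lineage_trait_timeaverage(
    samples: Sequence[tuple[float, float]],
    t_start: float,
    dt: float,
    n: int,
    atol: float = 1e-9,
) -> float:
    """Time-averaged lineage trait: mean of x(t_i) at t_i = t_start + i*dt,
    i = 0..n (n+1 samples).

    ``samples`` is the concatenation of the trait series of every cell along
    one lineage.  A missing grid time raises with the full list of gaps.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    times = np.array([t for t, _ in samples], dtype=float)
    values = np.array([x for _, x in samples], dtype=float)
    grid = t_start + dt * np.arange(n + 1)
    picked = np.empty(n + 1)
    missing = []
    for i, t in enumerate(grid):
        hits = np.nonzero(np.abs(times - t) <= atol)[0]
        if hits.size == 0:
            missing.append(float(t))
        else:
            picked[i] = values[hits[0]]
    if missing:
        raise ValueError(f"missing trait samples at times {missing}")
    return float(picked.mean())


def attach_timeaveraged_trait(
    ensemble: LineageEnsemble,
    series: Iterable[TraitSeries] | pd.DataFrame,
    trait: str,
    dt: float,
) -> LineageEnsemble:
    """Attach per-lineage time-averaged trait values to a tree-mode ensemble.

    The lineage path (recorded by :func:`parse_cell_table`) decides which
    cell's series supplies the sample at each grid time: the daughter on the
    path inherits the lineage across a division.
    """
    if ensemble.paths is None:
        raise ValueError("ensemble carries no cell paths; build it with parse_cell_table")
    if isinstance(series, pd.DataFrame):
        grouped: dict[str, list[tuple[float, float]]] = {}
        sub = series[series["trait"] == trait]
        for r in sub.itertuples(index=False):
            grouped.setdefault(str(r.cell_id), []).append((float(r.time), float(r.value)))
        series_map = {cid: sorted(v) for cid, v in grouped.items()}
    else:
        series_map = {s.cell_id: list(s.samples) for s in series if s.trait_name == trait}

    n = int(round(ensemble.tau / dt))
    values = []
    for rec in ensemble.records:
        path_samples: list[tuple[float, float]] = []
        for cid in ensemble.paths[rec.lineage_id]:
            path_samples.extend(series_map.get(cid, []))
        path_samples.sort()
        # across a division both mother (at her last time) and daughter may
        # carry a sample at the same t; the first (mother's) is used
        values.append(lineage_trait_timeaverage(path_samples, ensemble.t_start, dt, n))
    return ensemble.with_traits(trait, values)


# ---------------------------------------------------------------------------
# flat-file I/O
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ["cell_id", "parent_id", "birth_time", "end_time", "fate"]


def read_cell_table(path: str | Path, units: str = "hr") -> list[CellRecord]:
    """Read a cell edge-list TSV (header cell_id/parent_id/birth_time/end_time/fate)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "parent_id": str})
    missing = set(_CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cell table {path} lacks columns {sorted(missing)}")
    scale = _time_scale(units)
    return [
        CellRecord(
            str(r.cell_id),
            None if pd.isna(r.parent_id) or r.parent_id == "" else str(r.parent_id),
            float(r.birth_time) * scale,
            float(r.end_time) * scale,
            str(r.fate),
        )
        for r in df.itertuples(index=False)
    ]


def write_cell_table(rows: Iterable[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "parent_id": "" if c.parent_id is None else c.parent_id,
                "birth_time": c.birth_time,
                "end_time": c.end_time,
                "fate": c.fate,
            }
            for c in rows
        ],
        columns=_CELL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _time_scale(units: str) -> float:
    if units in ("hr", "h", "hours"):
        return 1.0
    if units in ("min", "minutes"):
        return 1.0 / 60.0
    raise ValueError(f"unknown time units {units!r}")


def write_lineage_table(ensemble: LineageEnsemble, path: str | Path) -> None:
    """Write lineage table TSV plus a JSON sidecar with the ensemble metadata."""
    path = Path(path)
    traits = ensemble.trait_names
    df = pd.DataFrame(
        [
            {"lineage_id": r.lineage_id, "division_count": r.divisions,
             **{t: r.traits.get(t, np.nan) for t in traits}}
            for r in ensemble.records
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "mode": ensemble.mode,
        "N0": ensemble.n0,
        "Ntau": ensemble.n_tau,
        "t_start": ensemble.t_start,
        "t_end": ensemble.t_end,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_lineage_table(path: str | Path) -> LineageEnsemble:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"lineage_id": str})
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    trait_cols = [c for c in df.columns if c not in ("lineage_id", "division_count")]
    records = [
        LineageRecord(
            str(r.lineage_id),
            int(r.division_count),
            {t: float(getattr(r, t)) for t in trait_cols if not pd.isna(getattr(r, t))},
        )
        for r in df.itertuples(index=False)
    ]
    return LineageEnsemble(
        meta["mode"], records, float(meta["N0"]), float(meta["t_start"]),
        float(meta["t_end"]),
        n_tau=None if meta.get("Ntau") is None else float(meta["Ntau"]),
    )


def read_trait_series(path: str | Path) -> pd.DataFrame:
    """Read a long trait-series TSV with columns cell_id/time/trait/value."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "trait": str})
    needed = {"cell_id", "time", "trait", "value"}
    if not needed <= set(df.columns):
        raise ValueError(f"trait series {path} lacks columns {sorted(needed - set(df.columns))}")
    return df
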
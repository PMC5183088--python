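"""Presence/absence survey data, quadrat lattices and their file formats.

The study design this package targets is a two-season resurvey of a fixed
quadrat grid: every species' presence (1) or absence (0) is recorded in every
quadrat in each of two census years.  Quadrats live on a rectangular lattice
and carry a binary canopy-gap flag; spatial structure enters the model through
the lattice adjacency.

Two on-disk dialects are supported:

* a pair of plain CSV tables (long survey table + quadrat attribute table);
* the BUGS/R-dump dialect with objects ``y1``, ``y2``, ``plot`` and the
  adjacency vectors ``adj``, ``weights``, ``num`` (the layout used by
  WinBUGS/OpenBUGS spatial models).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PresenceAbsenceSurvey",
    "QuadratLattice",
    "build_adjacency",
    "filter_species",
    "read_survey_csv",
    "write_survey_csv",
    "read_bugs_dump",
    "write_bugs_dump",
]

_ROOK_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN_OFFSETS = _ROOK_OFFSETS + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class PresenceAbsenceSurvey:
    """Species x quadrat binary detection matrices for two census years."""

    species_ids: list[str]
    quadrat_ids: list[str]
    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=np.int8)
        self.y2 = np.asarray(self.y2, dtype=np.int8)
        S, J = len(self.species_ids), len(self.quadrat_ids)
        if self.y1.shape != (S, J) or self.y2.shape != (S, J):
            raise ValueError(
                f"survey matrices must be ({S}, {J}); got {self.y1.shape} and {self.y2.shape}"
            )
        for name, y in (("y1", self.y1), ("y2", self.y2)):
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"{name} must contain only 0/1 entries")
        if len(set(self.species_ids)) != S:
            raise ValueError("species_ids must be unique")
        if len(set(self.quadrat_ids)) != J:
            raise ValueError("quadrat_ids must be unique")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_quadrats(self) -> int:
        return len(self.quadrat_ids)

    def detections_per_species(self) -> np.ndarray:
        """Total detection records per species, summed over quadrats and both years."""
        return self.y1.sum(axis=1) + self.y2.sum(axis=1)

    def quadrats_occupied_per_species(self) -> np.ndarray:
        """Number of quadrats where each species was seen in at least one year."""
        return (self.y1 | self.y2).sum(axis=1)


@dataclass
class QuadratLattice:
    """Quadrat lattice: adjacency relation, gap flags and (optionally) grid coords.

    ``adjacency`` is a symmetric 0/1 sparse matrix with zero diagonal
    (w_jk = 1 iff quadrats j and k are neighbours); ``gap`` is the binary
    canopy-gap covariate g_j.  ``coords`` holds (row, col) grid positions when
    known (CSV / generated lattices); lattices reconstructed from a BUGS dump
    carry only the adjacency and have ``coords=None``.
    """

    quadrat_ids: list[str]
    adjacency: sp.csr_matrix
    gap: np.ndarray
    coords: np.ndarray | None = None
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency, dtype=np.int8)
        self.gap = np.asarray(self.gap, dtype=np.int8)
        J = len(self.quadrat_ids)
        if len(set(self.quadrat_ids)) != J:
            raise ValueError("quadrat_ids must be unique")
        if self.adjacency.shape != (J, J):
            raise ValueError("adjacency must be square of side n_quadrats")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")
        if (self.adjacency != self.adjacency.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if not np.isin(self.adjacency.data, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if self.gap.shape != (J,) or not np.isin(self.gap, (0, 1)).all():
            raise ValueError("gap must be a binary vector of length n_quadrats")
        if (self.neighbor_count == 0).any():
            isolated = [self.quadrat_ids[j] for j in np.where(self.neighbor_count == 0)[0]]
            raise ValueError(f"isolated quadrats (no neighbours): {isolated}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=int)
            if self.coords.shape != (J, 2):
                raise ValueError("coords must be (n_quadrats, 2)")

    @property
    def n_quadrats(self) -> int:
        return len(self.quadrat_ids)

    @property
    def neighbor_count(self) -> np.ndarray:
        """w_j+ — number of neighbours of each quadrat."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        """Number of undirected neighbour pairs."""
        return self.adjacency.nnz // 2

    def is_connected(self) -> bool:
        n, _ = connected_components(self.adjacency, directed=False)
        return n == 1

    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian D - W of the adjacency (the ICAR structure matrix)."""
        deg = sp.diags(self.neighbor_count.astype(np.float64))
        return sp.csr_matrix(deg - self.adjacency.astype(np.float64))

    def edges(self) -> np.ndarray:
        """Undirected edge list as an (n_edges, 2) array of indices with j < k."""
        coo = self.adjacency.tocoo()
        mask = coo.row < coo.col
        return np.column_stack((coo.row[mask], coo.col[mask]))


def _adjacency_from_coords(coords: np.ndarray, rule: str) -> sp.csr_matrix:
    offsets = {"rook": _ROOK_OFFSETS, "queen": _QUEEN_OFFSETS}.get(rule)
    if offsets is None:
        raise ValueError(f"unknown neighbourhood rule {rule!r}; use 'rook' or 'queen'")
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    if len(index) != len(coords):
        raise ValueError("duplicate grid coordinates")
    rows, cols = [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    J = len(coords)
    return sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(J, J)
    )


def build_adjacency(
    n_rows: int,
    n_cols: int,
    gap_ids: set[str] | None = None,
    rule: str = "rook",
) -> QuadratLattice:
    """Construct the full rectangular lattice with rook (default) or queen adjacency.

    Quadrats are labelled ``q1`` ... ``qJ`` in row-major order (the 1-based
    order also used by the BUGS-dump dialect).
    """
    if n_rows * n_cols < 2:
        raise ValueError("lattice needs at least 2 quadrats")
    coords = np.array([(r, c) for r in range(n_rows) for c in range(n_cols)])
    quadrat_ids = [f"q{i + 1}" for i in range(n_rows * n_cols)]
    gap_ids = set(gap_ids or ())
    unknown = gap_ids - set(quadrat_ids)
    if unknown:
        raise ValueError(f"gap_ids outside grid: {sorted(unknown)}")
    gap = np.array([1 if q in gap_ids else 0 for q in quadrat_ids], dtype=np.int8)
    return QuadratLattice(
        quadrat_ids=quadrat_ids,
        adjacency=_adjacency_from_coords(coords, rule),
        gap=gap,
        coords=coords,
    )


def filter_species(
    survey: PresenceAbsenceSurvey,
    min_records: int = 5,
    count: str = "records",
) -> PresenceAbsenceSurvey:
    """Retain species observed in *more than* ``min_records`` detection records.

    With ``count="records"`` (default) a record is one (quadrat, year)
    detection, so totals are taken over both census years out of
    n_quadrats x 2 possible records.  ``count="quadrats"`` instead counts
    quadrats where the species was seen in either year (the union reading).
    The inequality is strict: a species with exactly ``min_records`` records
    is dropped.
    """
    if min_records < 0:
        raise ValueError("min_records must be >= 0")
    if count == "records":
        totals = survey.detections_per_species()
    elif count == "quadrats":
        totals = survey.quadrats_occupied_per_species()
    else:
        raise ValueError(f"unknown count rule {count!r}")
    keep = totals > min_records
    if not keep.any():
        raise ValueError(
            f"no species retained with min_records={min_records}; lower the threshold"
        )
    return PresenceAbsenceSurvey(
        species_ids=[s for s, k in zip(survey.species_ids, keep) if k],
        quadrat_ids=list(survey.quadrat_ids),
        y1=survey.y1[keep],
        y2=survey.y2[keep],
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_survey_csv(
    survey_path, quadrat_path, rule: str = "rook"
) -> tuple[PresenceAbsenceSurvey, QuadratLattice]:
    """Read the long-format survey table plus the quadrat attribute table.

    The survey table has columns (species, quadrat, year, presence); rows for
    absent (species, quadrat, year) combinations may be omitted and are filled
    with 0 — omission means confirmed absence, since each quadrat was searched
    exhaustively.  The quadrat table has columns (quadrat, row, col, gap) and
    fixes the quadrat ordering; adjacency is rebuilt from the grid coordinates.
    """
    qdf = pd.read_csv(quadrat_path)
    for col in ("quadrat", "row", "col", "gap"):
        if col not in qdf.columns:
            raise ValueError(f"quadrat table missing column {col!r}")
    quadrat_ids = [str(q) for q in qdf["quadrat"]]
    if len(set(quadrat_ids)) != len(quadrat_ids):
        raise ValueError("duplicate quadrat labels in quadrat table")
    gap = qdf["gap"].to_numpy()
    if not np.isin(gap, (0, 1)).all():
        raise ValueError("gap column must be 0/1")
    coords = qdf[["row", "col"]].to_numpy(dtype=int)
    lattice = QuadratLattice(
        quadrat_ids=quadrat_ids,
        adjacency=_adjacency_from_coords(coords, rule),
        gap=gap,
        coords=coords,
    )

    sdf = pd.read_csv(survey_path)
    for col in ("species", "quadrat", "year", "presence"):
        if col not in sdf.columns:
            raise ValueError(f"survey table missing column {col!r}")
    if sdf.duplicated(["species", "quadrat", "year"]).any():
        raise ValueError("duplicate (species, quadrat, year) rows")
    if not np.isin(sdf["presence"].to_numpy(), (0, 1)).all():
        raise ValueError("presence must be 0 or 1")
    years = sorted(sdf["year"].unique())
    if len(years) != 2:
        raise ValueError(f"expected exactly two census years, found {years}")
    unknown_q = set(sdf["quadrat"].astype(str)) - set(quadrat_ids)
    if unknown_q:
        raise ValueError(f"survey references unknown quadrats: {sorted(unknown_q)}")

    species_ids = list(dict.fromkeys(str(s) for s in sdf["species"]))
    srow = {s: i for i, s in enumerate(species_ids)}
    qcol = {q: j for j, q in enumerate(quadrat_ids)}
    S, J = len(species_ids), len(quadrat_ids)
    y1 = np.zeros((S, J), dtype=np.int8)
    y2 = np.zeros((S, J), dtype=np.int8)
    mats = {years[0]: y1, years[1]: y2}
    for sp_, q, yr, p in zip(
        sdf["species"], sdf["quadrat"], sdf["year"], sdf["presence"]
    ):
        mats[yr][srow[str(sp_)], qcol[str(q)]] = p
    survey = PresenceAbsenceSurvey(species_ids, quadrat_ids, y1, y2)
    return survey, lattice


def write_survey_csv(
    survey: PresenceAbsenceSurvey,
    lattice: QuadratLattice,
    survey_path,
    quadrat_path,
    years: tuple[int, int] = (1992, 2014),
    presences_only: bool = True,
) -> None:
    """Write the CSV pair read back by :func:`read_survey_csv`.

    By default only presence rows are written (absences are implied); pass
    ``presences_only=False`` to list every (species, quadrat, year) cell.
    """
    if lattice.coords is None:
        raise ValueError("lattice has no grid coordinates; cannot write quadrat table")
    rows = []
    # group rows by species so the reader's first-appearance species order
    # reproduces the writer's ordering
    for i, sp_ in enumerate(survey.species_ids):
        for yr, y in zip(years, (survey.y1, survey.y2)):
            cols = np.nonzero(y[i])[0] if presences_only else range(survey.n_quadrats)
            for j in cols:
                rows.append((sp_, survey.quadrat_ids[j], yr, int(y[i, j])))
    pd.DataFrame(rows, columns=["species", "quadrat", "year", "presence"]).to_csv(
        survey_path, index=False
    )
    qdf = pd.DataFrame(
        {
            "quadrat": lattice.quadrat_ids,
            "row": lattice.coords[:, 0],
            "col": lattice.coords[:, 1],
            "gap": lattice.gap,
        }
    )
    qdf.to_csv(quadrat_path, index=False)


# ---------------------------------------------------------------------------
# BUGS / R-dump dialect
# ---------------------------------------------------------------------------

_ASSIGN_RE = re.compile(r"(`?[A-Za-z.][A-Za-z0-9._]*`?)\s*<-")
_NUMBER_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _balanced_paren(text: str, start: int) -> str:
    """Return the content of the parenthesised expression opening at ``start``."""
    depth = 0
    for i in range(start, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return text[start + 1 : i]
    raise ValueError("unbalanced parentheses in R dump")


def _parse_rdump(text: str) -> dict[str, np.ndarray | float]:
    objs: dict[str, np.ndarray | float] = {}
    matches = list(_ASSIGN_RE.finditer(text))
    for m, nxt in zip(matches, matches[1:] + [None]):
        name = m.group(1).strip("`")
        chunk = text[m.end() : nxt.start() if nxt is not None else len(text)].strip()
        if chunk.startswith("structure"):
            dim_m = re.search(r"\.Dim\s*=\s*c\(([^)]*)\)", chunk)
            if dim_m is None:
                raise ValueError(f"structure() for {name!r} lacks .Dim")
            dims = [int(float(x)) for x in dim_m.group(1).split(",")]
            data_start = chunk.index("c(", len("structure"))
            inner = _balanced_paren(chunk, data_start + 1)
            vals = np.array([float(v) for v in _NUMBER_RE.findall(inner)])
            if vals.size != int(np.prod(dims)):
                raise ValueError(f"{name!r}: data length does not match .Dim {dims}")
            # R stores matrices column-major
            objs[name] = vals.reshape(dims, order="F")
        elif chunk.startswith("c("):
            inner = _balanced_paren(chunk, chunk.index("("))
            objs[name] = np.array([float(v) for v in _NUMBER_RE.findall(inner)])
        else:
            num = _NUMBER_RE.match(chunk)
            if num is None:
                raise ValueError(f"cannot parse value of {name!r}")
            objs[name] = float(num.group(0))
    return objs


def _adjacency_from_bugs(adj: np.ndarray, num: np.ndarray, J: int) -> sp.csr_matrix:
    """Rebuild w_jk from the run-length (adj, num) encoding; adj is 1-based."""
    num = num.astype(int)
    adj = adj.astype(int)
    if num.size != J:
        raise ValueError(f"num has length {num.size}, expected {J}")
    if num.sum() != adj.size:
        raise ValueError(f"sum(num)={num.sum()} does not equal length(adj)={adj.size}")
    if adj.size and (adj.min() < 1 or adj.max() > J):
        raise ValueError("adj references quadrats outside 1..J")
    rows = np.repeat(np.arange(J), num)
    cols = adj - 1
    A = sp.csr_matrix((np.ones(adj.size, dtype=np.int8), (rows, cols)), shape=(J, J))
    if (A != A.T).nnz != 0:
        raise ValueError("reconstructed adjacency is asymmetric")
    if A.diagonal().any():
        raise ValueError("reconstructed adjacency has self-neighbours")
    return A


def read_bugs_dump(path) -> tuple[PresenceAbsenceSurvey, QuadratLattice]:
    """Read the R-dump dialect with objects y1, y2, plot, adj, weights, num.

    ``plot`` is a (J, 3) matrix whose columns are (position, slope, affect);
    only ``affect`` — the gap flag — enters the model, but all three are
    parsed and kept on :attr:`QuadratLattice.extra`.
    """
    with open(path) as fh:
        objs = _parse_rdump(fh.read())
    for name in ("y1", "y2", "adj", "num"):
        if name not in objs:
            raise ValueError(f"R dump missing object {name!r}")
    y1 = np.asarray(objs["y1"])
    y2 = np.asarray(objs["y2"])
    if y1.ndim != 2 or y1.shape != y2.shape:
        raise ValueError("y1/y2 must be matrices of identical shape")
    S, J = y1.shape
    A = _adjacency_from_bugs(np.atleast_1d(objs["adj"]), np.atleast_1d(objs["num"]), J)
    weights = objs.get("weights")
    if weights is not None and not np.all(np.atleast_1d(weights) == 1):
        raise ValueError("only unit adjacency weights are supported")
    plot = objs.get("plot")
    extra = None
    if plot is not None:
        plot = np.atleast_2d(np.asarray(plot))
        if plot.shape[0] != J or plot.shape[1] < 3:
            raise ValueError("plot must be (n_quadrats, 3): position, slope, affect")
        gap = plot[:, 2].astype(np.int8)
        extra = pd.DataFrame(plot[:, :2], columns=["position", "slope"])
    else:
        gap = np.zeros(J, dtype=np.int8)
    survey = PresenceAbsenceSurvey(
        species_ids=[f"sp{i + 1}" for i in range(S)],
        quadrat_ids=[f"q{j + 1}" for j in range(J)],
        y1=y1,
        y2=y2,
    )
    lattice = QuadratLattice(
        quadrat_ids=list(survey.quadrat_ids), adjacency=A, gap=gap, extra=extra
    )
    return survey, lattice


def _fmt_vector(x: np.ndarray, int_ok: bool = True) -> str:
    vals = []
    for v in np.asarray(x).ravel(order="F"):
        if int_ok and float(v).is_integer():
            vals.append(str(int(v)))
        else:
            vals.append(repr(float(v)))
    return "c(" + ", ".join(vals) + ")"


def write_bugs_dump(
    survey: PresenceAbsenceSurvey, lattice: QuadratLattice, path
) -> None:
    """Write the R-dump dialect read back by :func:`read_bugs_dump`."""
    S, J = survey.n_species, survey.n_quadrats
    A = lattice.adjacency.tolil()
    adj, num = [], []
    for j in range(J):
        nb = sorted(A.rows[j])
        num.append(len(nb))
        adj.extend(k + 1 for k in nb)  # 1-based in the dump
    if lattice.extra is not None:
        position = lattice.extra["position"].to_numpy()
        slope = lattice.extra["slope"].to_numpy()
    else:
        position = np.zeros(J)
        slope = np.zeros(J)
    plot = np.column_stack((position, slope, lattice.gap)).astype(float)
    with open(path, "w") as fh:
        fh.write(f"y1 <- structure({_fmt_vector(survey.y1)}, .Dim = c({S}, {J}))\n")
        fh.write(f"y2 <- structure({_fmt_vector(survey.y2)}, .Dim = c({S}, {J}))\n")
        fh.write(f"plot <- structure({_fmt_vector(plot)}, .Dim = c({J}, 3))\n")
        fh.write(f"adj <- {_fmt_vector(np.array(adj))}\n")
        fh.write(f"weights <- {_fmt_vector(np.ones(len(adj)))}\n")
        fh.write(f"num <- {_fmt_vector(np.array(num))}\n")
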
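"""Readers and writers for every external artifact.

Similarity matrices, activity tables, fingerprint sets, coordinate
tables, gridded surfaces and evaluation reports all pass through this
module.  All formats are delimited text (plus a JSON sidecar for grid
metadata and a PNG contour render), so artifacts survive plain-text
round trips.  Floats are written with shortest round-trip ``repr`` so
``read(write(X)) == X`` holds bit-exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_DELIMITERS = ("\t", ",", ";")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Labelled square matrix of pairwise similarities in [0, 1].

    Attributes
    ----------
    ids : list of str
        Molecule identifiers, one per row/column, in matrix order.
    values : ndarray of shape (M, M)
        Symmetric similarity values with unit diagonal.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        validate_similarity(self.ids, self.values)

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return the sub-similarity-matrix restricted to ``ids`` (in that order)."""
        idx = _index_of(self.ids, ids, "similarity matrix")
        return SimilarityMatrix([self.ids[i] for i in idx],
                                self.values[np.ix_(idx, idx)])

    def rows(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        """Similarity rows of ``row_ids`` against ``col_ids`` (Q x M block)."""
        ri = _index_of(self.ids, row_ids, "similarity matrix")
        ci = _index_of(self.ids, col_ids, "similarity matrix")
        return self.values[np.ix_(ri, ci)]


@dataclass
class ActivityTable:
    """Binary activity labels, optionally with the Ki values they came from."""

    ids: list[str]
    labels: np.ndarray                    # int {0, 1}
    ki: np.ndarray | None = None          # nM, aligned with ids; NaN if absent
    cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate molecule ids: {dupes[:5]}")
        if len(self.ids) == 0:
            raise ValidationError("empty activity table")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
        if self.ki is not None:
            self.ki = np.asarray(self.ki, dtype=float)
            if self.cutoff_nm is not None:
                derived = (self.ki <= self.cutoff_nm).astype(int)
                ok = np.isnan(self.ki) | (derived == self.labels)
                if not ok.all():
                    bad = self.ids[int(np.argmin(ok))]
                    raise ValidationError(
                        f"label of {bad!r} inconsistent with Ki and cutoff")

    def label_of(self, ids: Sequence[str]) -> np.ndarray:
        idx = _index_of(self.ids, ids, "activity table")
        return self.labels[idx]


@dataclass
class FingerprintSet:
    """Binary structural fingerprints, one fixed-width bit row per molecule."""

    ids: list[str]
    bits: np.ndarray                      # (M, B) in {0, 1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValidationError("fingerprints must form a 2D bit matrix")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("fingerprint entries must be 0/1")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _index_of(universe: Sequence[str], wanted: Sequence[str], what: str) -> list[int]:
    pos = {m: i for i, m in enumerate(universe)}
    missing = [m for m in wanted if m not in pos]
    if missing:
        raise ValidationError(f"ids missing from {what}: {missing[:10]}")
    return [pos[m] for m in wanted]


def sniff_delimiter(path: str | os.PathLike) -> str:
    """Pick the delimiter among tab/comma/semicolon; ties go to tab."""
    with open(path) as fh:
        head = fh.readline()
    counts = [(head.count(d), -i) for i, d in enumerate(_DELIMITERS)]
    best = max(range(len(_DELIMITERS)), key=lambda i: counts[i])
    if counts[best][0] == 0:
        return "\t"
    return _DELIMITERS[best]


def validate_similarity(ids: Sequence[str], values: np.ndarray,
                        tolerance: float = 1e-8) -> None:
    m = values.shape[0] if values.ndim == 2 else -1
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"similarity matrix is not square: shape {values.shape}")
    if len(ids) != m:
        raise FormatError(f"{len(ids)} ids for a {m}x{m} matrix")
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(f"non-finite similarity at ({ids[i]}, {ids[j]})")
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > tolerance:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"asymmetry {asym[i, j]:.3g} > {tolerance:g} at ({ids[i]}, {ids[j]})")
    diag_err = np.abs(np.diag(values) - 1.0)
    if diag_err.max(initial=0.0) > tolerance:
        i = int(np.argmax(diag_err))
        raise ValidationError(f"diagonal of {ids[i]!r} is {values[i, i]!r}, not 1")
    lo, hi = values.min(), values.max()
    if lo < -tolerance or hi > 1 + tolerance:
        flat = np.argmax((values < -tolerance) | (values > 1 + tolerance))
        i, j = np.unravel_index(flat, values.shape)
        raise ValidationError(
            f"similarity {values[i, j]!r} outside [0,1] at ({ids[i]}, {ids[j]})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_similarity_matrix(path: str | os.PathLike,
                           tolerance: float = 1e-8) -> SimilarityMatrix:
    """Load a labelled square similarity matrix from delimited text.

    The first row and first column carry molecule ids.  Asymmetries no
    larger than ``tolerance`` are symmetrized by averaging; anything
    larger is an error (similarity producers are symmetric by
    construction, so big asymmetries signal corrupt input).
    """
    sep = sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0,
                         float_precision="round_trip")
    except Exception as exc:                       # pragma: no cover - pandas detail
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"similarity matrix is not square: shape {df.shape}")
    if ids != col_ids:
        raise FormatError("row ids and column ids differ (or are misordered)")
    values = df.to_numpy(dtype=float)
    validate_similarity(ids, values, tolerance)
    values = 0.5 * (values + values.T)             # kill sub-tolerance asymmetry
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values)


_NEG_WORDS = {"0", "inactive", "negative", "neg", "false"}
_POS_WORDS = {"1", "active", "positive", "pos", "true"}


def read_activity_table(path: str | os.PathLike,
                        cutoff_nm: float = 10.0) -> ActivityTable:
    """Load ``id, ki_nM`` or ``id, label`` delimited text.

    Ki rows become labels with positive iff Ki <= ``cutoff_nm``;
    pre-labelled rows ({1,0} or {active,inactive}) pass through.
    """
    if cutoff_nm <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff_nm}")
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str).dropna(how="all")
    if df.shape[1] < 2:
        raise FormatError("activity table needs an id column and a value column")
    if len(df) == 0:
        raise ValidationError("empty activity table")
    id_col, val_col = df.columns[0], df.columns[1]
    header = val_col.strip().lower()
    ids = [str(v).strip() for v in df[id_col]]
    raw = [str(v).strip() for v in df[val_col]]

    is_label_col = header in {"label", "class", "active"} or all(
        r.lower() in _NEG_WORDS | _POS_WORDS for r in raw)
    if is_label_col and not header.startswith("ki"):
        labels = []
        for mol, r in zip(ids, raw):
            low = r.lower()
            if low in _POS_WORDS:
                labels.append(1)
            elif low in _NEG_WORDS:
                labels.append(0)
            else:
                raise ValidationError(f"unrecognized label {r!r} for {mol!r}")
        return ActivityTable(ids, np.array(labels))

    try:
        ki = np.array([float(r) for r in raw])
    except ValueError as exc:
        raise ValidationError(f"non-numeric Ki value: {exc}") from exc
    if (ki <= 0).any():
        bad = ids[int(np.argmax(ki <= 0))]
        raise ValidationError(f"Ki of {bad!r} is not positive")
    labels = (ki <= cutoff_nm).astype(int)
    return ActivityTable(ids, labels, ki=ki, cutoff_nm=cutoff_nm)


def read_fingerprints(path: str | os.PathLike) -> FingerprintSet:
    """Load ``id, bitstring`` rows; bitstrings are '0'/'1' characters."""
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    ids = [str(v).strip() for v in df.iloc[:, 0]]
    strings = [str(v).strip() for v in df.iloc[:, 1]]
    widths = {len(s) for s in strings}
    if len(widths) != 1:
        raise FormatError(f"inconsistent fingerprint widths: {sorted(widths)}")
    if any(set(s) - {"0", "1"} for s in strings):
        raise FormatError("fingerprint strings may contain only '0'/'1'")
    bits = np.array([[int(c) for c in s] for s in strings], dtype=np.uint8)
    return FingerprintSet(ids, bits)


def fingerprints_from_smiles(ids: Sequence[str], smiles: Sequence[str],
                             n_bits: int = 2048, radius: int = 2) -> FingerprintSet:
    """Hashed circular fingerprints from SMILES via RDKit.

    Isolated adapter: RDKit is imported lazily so the core package never
    depends on it.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for mol_id, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"unparseable SMILES for {mol_id!r}: {smi!r}")
        fp = gen.GetFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=np.uint8))
    return FingerprintSet(list(ids), np.vstack(rows))


def tanimoto_similarity(fps: FingerprintSet) -> SimilarityMatrix:
    """Tanimoto coefficient matrix: |a AND b| / (|a| + |b| - |a AND b|)."""
    bits = fps.bits.astype(np.int64)
    if bits.shape[0] < 2:
        raise ValidationError("need at least 2 molecules for a similarity matrix")
    popcount = bits.sum(axis=1)
    if (popcount == 0).any():
        bad = fps.ids[int(np.argmax(popcount == 0))]
        raise ValidationError(f"all-zero fingerprint for {bad!r}: Tc undefined")
    inter = bits @ bits.T
    union = popcount[:, None] + popcount[None, :] - inter
    values = inter / union
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(fps.ids), values)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def write_similarity_matrix(sim: SimilarityMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for mol_id, row in zip(sim.ids, sim.values):
            fh.write(mol_id + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_activity_table(act: ActivityTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        if act.ki is not None:
            fh.write("id\tki_nM\n")
            for mol_id, ki in zip(act.ids, act.ki):
                fh.write(f"{mol_id}\t{_fmt(ki)}\n")
        else:
            fh.write("id\tlabel\n")
            for mol_id, lab in zip(act.ids, act.labels):
                fh.write(f"{mol_id}\t{int(lab)}\n")


def write_coordinates(path: str | os.PathLike, ids: Sequence[str],
                      coords: np.ndarray,
                      labels: np.ndarray | None = None,
                      split: Sequence[str] | None = None) -> None:
    coords = np.asarray(coords, dtype=float)
    labels = np.full(len(ids), -1) if labels is None else np.asarray(labels)
    split = ["train"] * len(ids) if split is None else list(split)
    with open(path, "w") as fh:
        fh.write("id\tx\ty\tlabel\tsplit\n")
        for mol_id, (x, y), lab, spl in zip(ids, coords, labels, split):
            fh.write(f"{mol_id}\t{_fmt(x)}\t{_fmt(y)}\t{int(lab)}\t{spl}\n")


def read_coordinates(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str},
                     float_precision="round_trip")
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    return df


def write_grid(path: str | os.PathLike, grid: np.ndarray,
               x_axis: np.ndarray, y_axis: np.ndarray,
               metadata: dict, sidecar_path: str | os.PathLike) -> None:
    """Write a gridded surface as TSV (rows = y axis) plus a JSON sidecar."""
    with open(path, "w") as fh:
        fh.write("y\\x\t" + "\t".join(_fmt(x) for x in x_axis) + "\n")
        for y, row in zip(y_axis, grid):
            fh.write(_fmt(y) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    with open(sidecar_path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_grid(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    x_axis = df.columns.to_numpy(dtype=float)
    y_axis = df.index.to_numpy(dtype=float)
    return df.to_numpy(dtype=float), x_axis, y_axis


def write_report(report: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_contour_png(path: str | os.PathLike, grid: np.ndarray,
                      x_axis: np.ndarray, y_axis: np.ndarray,
                      points: np.ndarray | None = None,
                      point_labels: np.ndarray | None = None,
                      title: str = "activity posterior") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    cs = ax.contourf(x_axis, y_axis, grid, levels=20, cmap="RdYlBu_r")
    fig.colorbar(cs, ax=ax, label="P(active | x, y)")
    if points is not None:
        points = np.asarray(points)
        if point_labels is None:
            ax.plot(points[:, 0], points[:, 1], "k.", ms=3)
        else:
            lab = np.asarray(point_labels).astype(bool)
            ax.plot(points[~lab, 0], points[~lab, 1], "k.", ms=3, label="inactive")
            ax.plot(points[lab, 0], points[lab, 1], "ro", ms=4, mfc="none",
                    label="active")
            ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ArtifactSet:
    """Paths written by :func:`write_artifacts`."""

    coordinates: str
    surface: str
    surface_meta: str
    contour: str
    report: str
    files: list[str] = field(default_factory=list)


def write_artifacts(outdir: str | os.PathLike, *,
                    ids: Sequence[str], coords: np.ndarray,
                    labels: np.ndarray, split: Sequence[str],
                    surface_grid: np.ndarray, x_axis: np.ndarray,
                    y_axis: np.ndarray, surface_meta: dict,
                    report: dict) -> ArtifactSet:
    """Write the full artifact set for one pipeline run into ``outdir``."""
    if not str(outdir):
        raise ValidationError("empty output directory path")
    os.makedirs(outdir, exist_ok=True)
    out = ArtifactSet(
        coordinates=os.path.join(outdir, "coordinates.tsv"),
        surface=os.path.join(outdir, "posterior_surface.tsv"),
        surface_meta=os.path.join(outdir, "posterior_surface.meta.json"),
        contour=os.path.join(outdir, "posterior_surface.png"),
        report=os.path.join(outdir, "report.json"),
    )
    write_coordinates(out.coordinates, ids, coords, labels, split)
    write_grid(out.surface, surface_grid, x_axis, y_axis, surface_meta,
               out.surface_meta)
    write_contour_png(out.contour, surface_grid, x_axis, y_axis,
                      points=np.asarray(coords), point_labels=np.asarray(labels))
    write_report(report, out.report)
    out.files = [out.coordinates, out.surface, out.surface_meta,
                 out.contour, out.report]
    return out
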
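"""Reading, writing, binning and normalising 1D NMR spectra and peak lists.

A :class:`Spectrum` stores intensities on a uniform ppm grid in the
descending-ppm convention of NMR display: index 0 sits at ``ppm_max`` (the
high-frequency edge) and the last index at ``ppm_min``.  All other modules
share this convention.

The default observation window matches a 250 MHz acquisition of 20.693 ppm
centred at 6.175 ppm, binned to 1024 points.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default observation window: 20.693 ppm centred at 6.175 ppm, 1024 points.
DEFAULT_PPM_MAX = 6.175 + 20.693 / 2.0
DEFAULT_PPM_MIN = 6.175 - 20.693 / 2.0
DEFAULT_N_POINTS = 1024


class SpectrumFormatError(ValueError):
    """A spectrum, prediction or assignment file violates its format."""


class DegenerateSpectrumError(ValueError):
    """An operation received a spectrum with no usable intensity."""


@dataclass(frozen=True)
class Spectrum:
    """A 1D spectrum on a uniform descending-ppm grid.

    Parameters
    ----------
    molecule_id:
        Text label identifying the molecule (or row) the spectrum belongs to.
    ppm_max, ppm_min:
        Chemical-shift positions of the first and last grid point.  The grid
        is ``linspace(ppm_max, ppm_min, n_points)``.
    intensities:
        Non-negative, finite intensities; index 0 at ``ppm_max``.
    """

    molecule_id: str
    ppm_max: float
    ppm_min: float
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.size < 2:
            raise SpectrumFormatError(
                f"spectrum '{self.molecule_id}' needs >= 2 points, got shape {arr.shape}"
            )
        if not self.ppm_max > self.ppm_min:
            raise SpectrumFormatError(
                f"ppm_max ({self.ppm_max}) must exceed ppm_min ({self.ppm_min})"
            )
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise SpectrumFormatError(
                f"spectrum '{self.molecule_id}' has a non-finite intensity at index {bad}"
            )
        if np.any(arr < 0):
            raise SpectrumFormatError(
                f"spectrum '{self.molecule_id}' has negative intensities; "
                "clip them on load (see clip_negative)"
            )

    @property
    def n_points(self) -> int:
        return int(self.intensities.size)

    @property
    def delta(self) -> float:
        """Grid spacing in ppm (positive)."""
        return (self.ppm_max - self.ppm_min) / (self.n_points - 1)

    def ppm_grid(self) -> np.ndarray:
        """Grid point positions, descending from ``ppm_max`` to ``ppm_min``."""
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)

    def total(self) -> float:
        return float(self.intensities.sum())

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.molecule_id, self.ppm_max, self.ppm_min, intensities)

    def same_grid(self, other: "Spectrum", tol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and abs(self.ppm_max - other.ppm_max) <= tol
            and abs(self.ppm_min - other.ppm_min) <= tol
        )


@dataclass(frozen=True)
class ProtonGroup:
    """A group of equivalent protons: shift, multiplicity and couplings.

    ``couplings`` is a list of ``(J_hz, n_partners)`` pairs; each entry splits
    the resonance by ``n_partners`` equivalent spin-1/2 partners.
    """

    shift: float
    n_protons: int
    couplings: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError(f"n_protons must be >= 1, got {self.n_protons}")
        if not math.isfinite(self.shift):
            raise ValueError("shift must be finite")
        for j, n in self.couplings:
            if j < 0 or n < 1:
                raise ValueError(f"invalid coupling (J={j}, n_partners={n})")


@dataclass(frozen=True)
class PredictionSet:
    """Per-molecule list of predicted proton groups."""

    molecule_id: str
    groups: tuple[ProtonGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"prediction for '{self.molecule_id}' has no groups")

    @property
    def total_protons(self) -> int:
        return sum(g.n_protons for g in self.groups)


@dataclass(frozen=True)
class AssignmentTable:
    """Assigned (observed, predicted) shift pairs for one molecule."""

    molecule_id: str
    pairs: tuple[tuple[float, float], ...] = ()

    def errors(self) -> np.ndarray:
        """Absolute deviations |observed - predicted| in ppm."""
        if not self.pairs:
            return np.empty(0)
        arr = np.asarray(self.pairs, dtype=float)
        return np.abs(arr[:, 0] - arr[:, 1])


def clip_negative(intensities: np.ndarray, molecule_id: str = "") -> np.ndarray:
    """Clip negative baseline artifacts to zero, logging how many were hit."""
    arr = np.asarray(intensities, dtype=float)
    n_neg = int((arr < 0).sum())
    if n_neg:
        logger.info("clipped %d negative intensities in '%s'", n_neg, molecule_id)
        arr = np.clip(arr, 0.0, None)
    return arr


# ---------------------------------------------------------------------------
# JCAMP-DX

_LDR = re.compile(r"^##\s*([^=]*?)\s*=\s*(.*)$")


def _jcamp_records(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    current: tuple[str, list[str]] | None = None
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        m = _LDR.match(line)
        if m:
            if current is not None:
                records.append((current[0], "\n".join(current[1])))
            label = m.group(1).upper().replace(" ", "").replace("-", "").replace("_", "")
            current = (label, [m.group(2)])
        elif current is not None and line.strip():
            current[1].append(line)
    if current is not None:
        records.append((current[0], "\n".join(current[1])))
    return records


def _parse_float(records: dict[str, str], key: str, path: Path) -> float:
    if key not in records:
        raise SpectrumFormatError(f"{path}: missing required JCAMP record ##{key}")
    try:
        return float(records[key].strip().split("\n")[0])
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: unreadable ##{key}={records[key]!r}") from exc


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a single 1D real JCAMP-DX block (##XYDATA or ##XYPOINTS form).

    The ppm axis is taken from FIRSTX/LASTX (scaled by XFACTOR); intensities
    are scaled by YFACTOR and re-oriented to descending ppm if the file stores
    them ascending.  Negative intensities are clipped to zero.
    """
    path = Path(path)
    pairs = _jcamp_records(path)
    records = dict(pairs)
    if "NTUPLES" in records or records.get("DATACLASS", "").strip().upper() == "NTUPLES":
        raise SpectrumFormatError(f"{path}: nD/NTUPLES data is not supported")

    xfactor = float(records.get("XFACTOR", "1").strip() or 1)
    yfactor = float(records.get("YFACTOR", "1").strip() or 1)
    firstx = _parse_float(records, "FIRSTX", path) * xfactor
    lastx = _parse_float(records, "LASTX", path) * xfactor

    if "XYDATA" in records:
        body = records["XYDATA"].split("\n")
        form = body[0].strip().upper()
        if "X++" not in form:
            raise SpectrumFormatError(f"{path}: unsupported ##XYDATA form {form!r}")
        ys: list[float] = []
        for line in body[1:]:
            vals = line.replace(",", " ").split()
            if not vals:
                continue
            # first value on each line is the X of that line's first Y
            ys.extend(float(v) for v in vals[1:])
        y = np.asarray(ys, dtype=float) * yfactor
    elif "XYPOINTS" in records or "PEAKTABLE" in records:
        key = "XYPOINTS" if "XYPOINTS" in records else "PEAKTABLE"
        body = records[key].split("\n")[1:]
        xs: list[float] = []
        ys = []
        for line in body:
            for pair in line.replace(";", " ").split():
                x_str, _, y_str = pair.partition(",")
                if not y_str:
                    raise SpectrumFormatError(f"{path}: malformed XY pair {pair!r}")
                xs.append(float(x_str))
                ys.append(float(y_str))
        order = np.argsort(xs)[::-1]  # descending ppm
        y = np.asarray(ys, dtype=float)[order] * yfactor
    else:
        raise SpectrumFormatError(
            f"{path}: no ##XYDATA or ##XYPOINTS data block found"
        )

    npoints = records.get("NPOINTS")
    if npoints is not None and int(float(npoints.strip().split("\n")[0])) != y.size:
        raise SpectrumFormatError(
            f"{path}: ##NPOINTS={npoints.strip()} but {y.size} intensities read"
        )
    if not np.all(np.isfinite(y)):
        raise SpectrumFormatError(f"{path}: non-finite intensity in data block")

    if firstx < lastx:  # ascending storage: mirror to descending-ppm convention
        y = y[::-1]
    ppm_max, ppm_min = max(firstx, lastx), min(firstx, lastx)
    title = records.get("TITLE", path.stem).strip() or path.stem
    return Spectrum(title, ppm_max, ppm_min, clip_negative(y, title))


def write_jcamp(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a minimal JCAMP-DX ##XYDATA=(X++(Y..Y)) block."""
    path = Path(path)
    lines = [
        f"##TITLE={s.molecule_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={s.ppm_max:.6f}",
        f"##LASTX={s.ppm_min:.6f}",
        f"##NPOINTS={s.n_points}",
        "##XYDATA=(X++(Y..Y))",
    ]
    grid = s.ppm_grid()
    per_line = 6
    for i in range(0, s.n_points, per_line):
        chunk = s.intensities[i : i + per_line]
        lines.append(
            f"{grid[i]:.6f} " + " ".join(f"{v:.10g}" for v in chunk)
        )
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Matrix format: one spectrum per row of a numeric text matrix

def read_spectrum_matrix(
    path: str | Path, ppm_max: float = DEFAULT_PPM_MAX, ppm_min: float = DEFAULT_PPM_MIN
) -> list[Spectrum]:
    """Read spectra stored one-per-row in a whitespace/CSV numeric matrix.

    Every row shares the declared ppm window; molecule ids are assigned
    ``row0001, row0002, ...`` in file order.
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = np.asarray(parts, dtype=float)
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: non-numeric value at line {lineno}"
                ) from exc
            if width is None:
                width = vals.size
            elif vals.size != width:
                raise SpectrumFormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({vals.size} values, expected {width})"
                )
            rows.append(vals)
    if not rows:
        raise SpectrumFormatError(f"{path}: empty spectrum matrix")
    return [
        Spectrum(f"row{i + 1:04d}", ppm_max, ppm_min, clip_negative(r, f"row{i + 1:04d}"))
        for i, r in enumerate(rows)
    ]


def write_spectrum_matrix(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra one per row; all must share the same grid."""
    if not spectra:
        raise ValueError("no spectra to write")
    ref = spectra[0]
    for s in spectra[1:]:
        if not ref.same_grid(s):
            raise ValueError(f"spectrum '{s.molecule_id}' is on a different grid")
    mat = np.vstack([s.intensities for s in spectra])
    np.savetxt(path, mat, fmt="%.10g")


# ---------------------------------------------------------------------------
# Binning and normalisation

def bin_spectrum(s: Spectrum, n_out: int) -> Spectrum:
    """Sum intensities into ``n_out`` equal-width bins spanning the window.

    Bins are half-open on the high-ppm side with the final bin closed, so
    every grid point lands in exactly one bin and total intensity is
    conserved.  The output grid points sit at the bin centres.
    """
    if n_out < 2:
        raise ValueError(f"n_out must be >= 2, got {n_out}")
    if n_out > s.n_points:
        raise ValueError(f"n_out ({n_out}) exceeds n_points ({s.n_points})")
    width = (s.ppm_max - s.ppm_min) / n_out
    # distance of each point below the high edge, in bin widths
    idx = np.floor((s.ppm_max - s.ppm_grid()) / width).astype(int)
    idx = np.clip(idx, 0, n_out - 1)
    out = np.bincount(idx, weights=s.intensities, minlength=n_out)
    centre0 = s.ppm_max - width / 2.0
    centre_last = s.ppm_max - (n_out - 0.5) * width
    return Spectrum(s.molecule_id, centre0, centre_last, out)


def normalize_total(s: Spectrum) -> Spectrum:
    """Scale intensities so they sum to exactly 1 (last bin absorbs rounding)."""
    total = s.total()
    if total <= 0:
        raise DegenerateSpectrumError(
            f"spectrum '{s.molecule_id}' has zero total intensity"
        )
    out = s.intensities / total
    out[-1] = max(0.0, 1.0 - out[:-1].sum())
    return s.with_intensities(out)


# ---------------------------------------------------------------------------
# Prediction and assignment tables (CSV dialect)

def _parse_couplings(text: str, where: str) -> tuple[tuple[float, int], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        j_str, sep, n_str = token.partition(":")
        try:
            j = float(j_str)
            n = int(n_str) if sep else 1
        except ValueError as exc:
            raise SpectrumFormatError(f"{where}: unparsable coupling {token!r}") from exc
        if j < 0 or n < 1:
            raise SpectrumFormatError(f"{where}: invalid coupling {token!r}")
        out.append((j, n))
    return tuple(out)


def _is_header(row: Sequence[str]) -> bool:
    if len(row) < 2:
        return False
    try:
        float(row[1])
        return False
    except ValueError:
        return True


def read_predictions(path: str | Path) -> list[PredictionSet]:
    """Read a prediction table: molecule_id, shift_ppm, n_protons[, couplings].

    Couplings use the ``J1:n1;J2:n2`` dialect (J in Hz, n equivalent
    partners).  Rows with the same molecule_id are merged into a single
    :class:`PredictionSet`, even across non-adjacent blocks; molecule order is
    first appearance.
    """
    path = Path(path)
    groups: dict[str, list[ProtonGroup]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row]
            if not row or not any(row) or row[0].startswith("#"):
                continue
            if lineno == 1 and _is_header(row):
                continue
            where = f"{path}:{lineno}"
            if len(row) < 3:
                raise SpectrumFormatError(f"{where}: expected >= 3 columns")
            mol = row[0]
            try:
                shift = float(row[1])
                n_protons = int(row[2])
            except ValueError as exc:
                raise SpectrumFormatError(f"{where}: non-numeric shift or count") from exc
            if n_protons < 1:
                raise SpectrumFormatError(f"{where}: n_protons must be >= 1")
            couplings = _parse_couplings(row[3] if len(row) > 3 else "", where)
            groups.setdefault(mol, []).append(ProtonGroup(shift, n_protons, couplings))
    if not groups:
        raise SpectrumFormatError(f"{path}: no prediction rows found")
    return [PredictionSet(mol, tuple(gs)) for mol, gs in groups.items()]


def write_predictions(preds: Iterable[PredictionSet], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule_id", "shift_ppm", "n_protons", "couplings"])
        for p in preds:
            for g in p.groups:
                coupling_str = ";".join(f"{j:g}:{n}" for j, n in g.couplings)
                writer.writerow([p.molecule_id, f"{g.shift:.6f}", g.n_protons, coupling_str])


def read_assignments(path: str | Path) -> list[AssignmentTable]:
    """Read an assignment table: molecule_id, observed_shift, predicted_shift."""
    path = Path(path)
    pairs: dict[str, list[tuple[float, float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row]
            if not row or not any(row) or row[0].startswith("#"):
                continue
            if lineno == 1 and _is_header(row):
                continue
            where = f"{path}:{lineno}"
            if len(row) < 3:
                raise SpectrumFormatError(f"{where}: expected 3 columns")
            try:
                obs, pred = float(row[1]), float(row[2])
            except ValueError as exc:
                raise SpectrumFormatError(f"{where}: non-numeric shift") from exc
            if not (math.isfinite(obs) and math.isfinite(pred)):
                raise SpectrumFormatError(f"{where}: non-finite shift")
            pairs.setdefault(row[0], []).append((obs, pred))
    if not pairs:
        raise SpectrumFormatError(f"{path}: no assignment rows found")
    return [AssignmentTable(mol, tuple(ps)) for mol, ps in pairs.items()]


def write_assignments(tables: Iterable[AssignmentTable], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule_id", "observed_shift", "predicted_shift"])
        for t in tables:
            for obs, pred in t.pairs:
                writer.writerow([t.molecule_id, f"{obs:.6f}", f"{pred:.6f}"])
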
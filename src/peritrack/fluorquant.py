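"""ROMIF photometry and polymerase counting.

The focus-intensity estimator of the experiment is the ROMIF — the 5×5-pixel
window with the maximum integrated fluorescence inside a cell.  The chain of
observables is

    I_max            = mean(ROMIF) − mean(cellular background)
    I_transcribing(t) = <I_max(t)> − <I_max(0)>
    count(t)          = I_transcribing(t) / <Ī_single>

where <Ī_single> is the per-pixel single-fluorophore unit, i.e. the mean
integrated 5×5 intensity of isolated single-fluorophore dots divided by 25.
Because the same 5×5 aperture is used for the unknown focus and for the
calibration dots, the PSF flux fraction captured by the window cancels in
the count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW = 5  # ROMIF aperture side, pixels

__all__ = [
    "RomifResult",
    "InductionSeries",
    "SingleFluorCalibration",
    "find_romif",
    "cellular_background",
    "i_max",
    "quantify_stack",
    "transcribing_intensity",
    "calibrate_single_fluorophore",
    "count_transcribing",
    "exclude_bright_cells",
]


@dataclass(frozen=True)
class RomifResult:
    """The maximizing 5×5 window of one cell."""

    origin: tuple[int, int]  # (row, col) of the window's top-left pixel
    integrated: float  # summed intensity over the 25 pixels
    mean: float  # integrated / 25

    def __post_init__(self) -> None:
        if not np.isclose(self.integrated, 25.0 * self.mean):
            raise ValueError("integrated must equal 25 x mean")


@dataclass
class InductionSeries:
    """Population-averaged induction time course.

    ``intensity`` holds I_transcribing(t) (counts/pixel); ``counts`` holds
    the calibrated mean number of transcribing polymerases per cell, filled
    in by :func:`count_transcribing`.
    """

    times_s: np.ndarray
    intensity: np.ndarray
    n: np.ndarray
    sd: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(np.asarray(self.n) < 1):
            raise ValueError("every time point needs n >= 1 cells")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"time_s": self.times_s, "i_transcribing": self.intensity, "n": self.n, "sd": self.sd}
        )
        if self.counts is not None:
            out["mean_count"] = self.counts
        return out


@dataclass(frozen=True)
class SingleFluorCalibration:
    """Single-fluorophore intensity unit from isolated membrane dots."""

    integrated: np.ndarray  # per-dot 5x5 integrated intensities
    unit: float  # mean(integrated) / 25, counts/pixel


def _window_sums(arr: np.ndarray) -> np.ndarray:
    """Sums over every 5×5 window via a 2D cumulative sum."""
    c = np.cumsum(np.cumsum(np.pad(arr, ((1, 0), (1, 0))), axis=0), axis=1)
    k = WINDOW
    return c[k:, k:] - c[:-k, k:] - c[k:, :-k] + c[:-k, :-k]


def find_romif(frame: np.ndarray, mask: np.ndarray, cell_id: int | None = None) -> RomifResult:
    """Locate the 5×5 window with the maximum integrated intensity in a cell.

    Only windows whose 25 pixels all lie inside the mask are candidates;
    ties are broken by the smallest row-major window origin.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    if min(frame.shape) < WINDOW:
        raise ValueError(
            f"cell {'' if cell_id is None else cell_id} image smaller than the 5x5 aperture"
        )
    valid = _window_sums(mask.astype(np.int64)) == WINDOW * WINDOW
    if not valid.any():
        label = "cell" if cell_id is None else f"cell {cell_id}"
        raise ValueError(f"{label} has no fully interior 5x5 window")
    sums = _window_sums(frame)
    sums = np.where(valid, sums, -np.inf)
    flat = int(np.argmax(sums))  # row-major: first maximum wins ties
    origin = np.unravel_index(flat, sums.shape)
    integrated = float(sums[origin])
    return RomifResult(origin=(int(origin[0]), int(origin[1])), integrated=integrated, mean=integrated / 25.0)


def cellular_background(frame: np.ndarray, mask: np.ndarray, romif: RomifResult) -> float:
    """Mean intensity over the cell mask excluding the 25 ROMIF pixels."""
    frame = np.asarray(frame, dtype=float)
    keep = np.asarray(mask, dtype=bool).copy()
    r, c = romif.origin
    keep[r : r + WINDOW, c : c + WINDOW] = False
    if not keep.any():
        raise ValueError("cell mask minus the ROMIF window is empty")
    return float(frame[keep].mean())


def i_max(frame: np.ndarray, mask: np.ndarray, cell_id: int | None = None) -> float:
    """Background-subtracted focus intensity, counts/pixel.

    mean(ROMIF) − mean(cellular background); approximately zero for cells
    without a focus.
    """
    romif = find_romif(frame, mask, cell_id=cell_id)
    return romif.mean - cellular_background(frame, mask, romif)


def exclude_bright_cells(cell_totals: pd.Series, percentile: float = 95.0) -> pd.Index:
    """Cells to keep after dropping the brightest tail.

    Mirrors the exclusion of cells with too many labeled polymerases, whose
    high diffuse background defeats focus detection.  Returns the index of
    cells at or below the given percentile of total cellular fluorescence.
    """
    cutoff = np.percentile(cell_totals.to_numpy(), percentile)
    return cell_totals.index[cell_totals.to_numpy() <= cutoff]


def quantify_stack(
    frames: np.ndarray,
    masks: np.ndarray,
    times_s,
    autofluorescence: float = 0.0,
    bright_percentile: float | None = 95.0,
) -> pd.DataFrame:
    """Per-cell I_max for every frame of a stack.

    ``masks`` is a label image (or per-frame stack of label images); cells
    too small for an interior 5×5 window are skipped.  ``autofluorescence``
    is a constant per-pixel level (measured from an unlabeled control
    strain) subtracted from each frame before photometry.  When
    ``bright_percentile`` is set, cells whose time-mean total fluorescence
    exceeds that percentile are excluded.
    """
    frames = np.asarray(frames, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != times.size:
        raise ValueError("frames must be (n_frames, H, W) matching times")
    static_mask = np.asarray(masks)
    per_frame = static_mask.ndim == 3

    rows = []
    totals: dict[int, list[float]] = {}
    for f in range(frames.shape[0]):
        label = static_mask[f] if per_frame else static_mask
        frame = frames[f] - autofluorescence
        for cid in np.unique(label):
            if cid == 0:
                continue
            sel = label == cid
            rr, cc = np.nonzero(sel)
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            sub_f = frame[r0:r1, c0:c1]
            sub_m = sel[r0:r1, c0:c1]
            totals.setdefault(int(cid), []).append(float(frame[sel].sum()))
            try:
                value = i_max(sub_f, sub_m, cell_id=int(cid))
            except ValueError:
                continue
            rows.append({"cell_id": int(cid), "time_s": times[f], "i_max": value})
    table = pd.DataFrame(rows)
    if bright_percentile is not None and not table.empty:
        means = pd.Series({cid: np.mean(v) for cid, v in totals.items()})
        keep = exclude_bright_cells(means, bright_percentile)
        table = table[table["cell_id"].isin(keep)].reset_index(drop=True)
    return table


def transcribing_intensity(per_cell: pd.DataFrame) -> InductionSeries:
    """Population-mean focus intensity above the pre-induction level.

    ``per_cell`` needs columns ``time_s`` and ``i_max`` and must include a
    time-0 (pre-induction) group; cells without a visible focus contribute
    their (near-zero) I_max rather than being dropped.
    """
    if not {"time_s", "i_max"}.issubset(per_cell.columns):
        raise ValueError("per-cell table needs 'time_s' and 'i_max' columns")
    grouped = per_cell.groupby("time_s")["i_max"]
    stats = grouped.agg(["mean", "count", "std"]).sort_index()
    if 0.0 not in stats.index:
        raise ValueError("no pre-induction (time 0) group in the series")
    baseline = stats.loc[0.0, "mean"]
    return InductionSeries(
        times_s=stats.index.to_numpy(),
        intensity=(stats["mean"] - baseline).to_numpy(),
        n=stats["count"].to_numpy(),
        sd=stats["std"].fillna(0.0).to_numpy(),
    )


def calibrate_single_fluorophore(dot_intensities) -> SingleFluorCalibration:
    """Per-pixel single-fluorophore unit from isolated-dot photometry.

    ``dot_intensities`` are integrated 5×5 intensities of single
    fluorophores; the unit is their mean divided by 25.  Fewer than 10 dots
    gives a warning (the calibration is then poorly determined).
    """
    dots = np.asarray(list(dot_intensities), dtype=float)
    if dots.size == 0:
        raise ValueError("calibration needs at least one dot intensity")
    if np.any(dots <= 0):
        raise ValueError("dot intensities must be positive")
    if dots.size < 10:
        warnings.warn(
            f"only {dots.size} calibration dots; >= 10 recommended", stacklevel=2
        )
    return SingleFluorCalibration(integrated=dots, unit=float(dots.mean() / 25.0))


def count_transcribing(
    series: InductionSeries, calibration: SingleFluorCalibration
) -> InductionSeries:
    """Convert I_transcribing(t) into mean transcribing polymerases per cell."""
    if calibration.unit <= 0:
        raise ValueError(f"calibration unit must be positive, got {calibration.unit!r}")
    series.counts = series.intensity / calibration.unit
    return series
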
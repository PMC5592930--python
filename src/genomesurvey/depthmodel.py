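"""Window construction, depth extraction, GC correction, and depth calibration.

The read-depth CNV framework works on nonoverlapping fixed-width windows
(500 bp by default) tiled across every scaffold.  Raw per-window depth is the
mean per-bp coverage.  Depth is then rescaled per GC class — each window's
depth is multiplied by (global mean depth) / (mean depth of windows with the
same GC fraction) — which removes the smooth amplification/coverage bias that
library preparation introduces as a function of GC.  Finally a Gaussian is
fitted to the corrected-depth histogram around its mode, and the calibrated
mean/SD define the duplication (mean + 3 SD) and deletion (mean − 2 SD)
cutoffs used by the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .seqio import GenomeSequence

log = logging.getLogger(__name__)

DEPTH_TABLE_HEADER = "#scaffold\tstart\tend\tdepth"


class CalibrationError(RuntimeError):
    pass


@dataclass
class DepthWindow:
    """One fixed-width window with raw/corrected depth and composition."""

    scaffold: str
    start: int
    end: int
    gc_fraction: float
    n_fraction: float
    raw_depth: float | None = None
    corrected_depth: float | None = None
    partial: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    def usable(self, max_n_fraction: float = 0.5) -> bool:
        """Windows dominated by assembly gaps carry meaningless depth."""
        return self.n_fraction <= max_n_fraction and not self.partial


@dataclass
class DepthCalibration:
    mean: float
    sd: float
    dup_multiplier: float = 3.0
    del_multiplier: float = 2.0
    gc_bin_means: dict[int, float] = field(default_factory=dict)
    gc_bin_width: float = 0.01
    fit_method: str = "gaussian"

    @property
    def dup_cutoff(self) -> float:
        return self.mean + self.dup_multiplier * self.sd

    @property
    def del_cutoff(self) -> float:
        return self.mean - self.del_multiplier * self.sd


def make_windows(
    assembly: Iterable[GenomeSequence], width: int = 500
) -> list[DepthWindow]:
    """Tile each scaffold left to right with nonoverlapping windows.

    The trailing window of a scaffold may be shorter than ``width``; it is
    kept but flagged partial (excluded from calibration and calling).
    """
    if width < 50:
        raise ValueError("window width must be >= 50 bp")
    windows: list[DepthWindow] = []
    for scaf in assembly:
        L = len(scaf)
        for start in range(0, L, width):
            end = min(start + width, L)
            chunk = scaf.seq[start:end]
            n = chunk.count("N")
            non_n = len(chunk) - n
            gc = (chunk.count("G") + chunk.count("C")) / non_n if non_n else 0.0
            windows.append(
                DepthWindow(
                    scaffold=scaf.name,
                    start=start,
                    end=end,
                    gc_fraction=gc,
                    n_fraction=n / len(chunk),
                    partial=(end - start) < width,
                )
            )
    return windows


# ---------------------------------------------------------------------------
# Depth extraction
# ---------------------------------------------------------------------------


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read the windowed depth-table dialect (0-based half-open).

    Columns: scaffold, start, end, depth; header line ``#scaffold\\tstart...``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment=None,
        names=["scaffold", "start", "end", "depth"],
        skiprows=1,
        dtype={"scaffold": str},
    )
    return df


def write_depth_table(windows: Sequence[DepthWindow], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(DEPTH_TABLE_HEADER + "\n")
        for w in windows:
            fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\t{w.raw_depth:.6g}\n")


def window_depth(
    windows: Sequence[DepthWindow],
    alignments: str | Path,
    min_mapq: int = 0,
) -> list[DepthWindow]:
    """Fill raw_depth from a BAM file or a depth-table TSV.

    raw_depth = (sum of aligned bp overlapping the window) / window length.
    From BAM, unmapped/secondary/duplicate reads and reads below ``min_mapq``
    are excluded.  From the TSV dialect, values are taken as-is (windows are
    matched on scaffold and start).
    """
    path = Path(alignments)
    if path.suffix == ".bam":
        return _window_depth_bam(windows, path, min_mapq)
    df = read_depth_table(path)
    known = {w.scaffold for w in windows}
    bad = sorted(set(df["scaffold"]) - known)
    if bad:
        raise ValueError(f"depth table names unknown scaffolds: {', '.join(bad)}")
    lookup = {(r.scaffold, int(r.start)): float(r.depth) for r in df.itertuples()}
    for w in windows:
        w.raw_depth = lookup.get((w.scaffold, w.start), 0.0)
    return list(windows)


def _window_depth_bam(
    windows: Sequence[DepthWindow], path: Path, min_mapq: int
) -> list[DepthWindow]:
    import pysam

    by_scaffold: dict[str, list[DepthWindow]] = {}
    for w in windows:
        by_scaffold.setdefault(w.scaffold, []).append(w)
    for wins in by_scaffold.values():
        wins.sort(key=lambda w: w.start)
    with pysam.AlignmentFile(str(path)) as bam:
        bad = sorted(set(bam.references) - set(by_scaffold))
        if bad:
            raise ValueError(f"BAM names unknown scaffolds: {', '.join(bad)}")
        cover: dict[str, np.ndarray] = {
            scaf: np.zeros(len(wins), dtype=np.float64)
            for scaf, wins in by_scaffold.items()
        }
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
            ):
                continue
            wins = by_scaffold.get(read.reference_name)
            if wins is None:
                continue
            width = wins[0].width
            for bstart, bend in read.get_blocks():
                i = max(0, bstart // width)
                while i < len(wins) and wins[i].start < bend:
                    ov = min(bend, wins[i].end) - max(bstart, wins[i].start)
                    if ov > 0:
                        cover[read.reference_name][i] += ov
                    i += 1
    for scaf, wins in by_scaffold.items():
        for i, w in enumerate(wins):
            w.raw_depth = cover[scaf][i] / w.width
    return list(windows)


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------


def gc_correct(
    windows: Sequence[DepthWindow],
    gc_bin_width: float = 0.01,
    min_bin_windows: int = 50,
    max_n_fraction: float = 0.5,
) -> DepthCalibration:
    """Rescale each window's depth by (global mean)/(its GC-bin mean).

    Windows with n_fraction above ``max_n_fraction`` (or partial trailing
    windows) are excluded from bin statistics; they still receive a corrected
    value so downstream code need not special-case missing fields, but remain
    flagged and never contribute to calibration or calls.  GC bins occupied by
    fewer than ``min_bin_windows`` usable windows fall back to a correction
    factor of 1.
    """
    usable = [w for w in windows if w.usable(max_n_fraction) and w.raw_depth is not None]
    if not usable:
        raise CalibrationError("no usable windows for GC correction")
    global_mean = float(np.mean([w.raw_depth for w in usable]))
    nbins = int(round(1.0 / gc_bin_width))
    sums = np.zeros(nbins + 1)
    counts = np.zeros(nbins + 1, dtype=np.int64)
    for w in usable:
        b = min(nbins, int(w.gc_fraction / gc_bin_width))
        sums[b] += w.raw_depth
        counts[b] += 1
    bin_means: dict[int, float] = {}
    for b in range(nbins + 1):
        if counts[b] >= min_bin_windows and sums[b] > 0:
            bin_means[b] = sums[b] / counts[b]
    for w in windows:
        if w.raw_depth is None:
            continue
        b = min(nbins, int(w.gc_fraction / gc_bin_width))
        m_gc = bin_means.get(b, global_mean)
        w.corrected_depth = w.raw_depth * global_mean / m_gc if m_gc > 0 else 0.0
    return DepthCalibration(
        mean=global_mean,
        sd=float("nan"),
        gc_bin_means=bin_means,
        gc_bin_width=gc_bin_width,
        fit_method="uncalibrated",
    )


# ---------------------------------------------------------------------------
# Gaussian calibration
# ---------------------------------------------------------------------------


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(
    windows_or_depths: Sequence[DepthWindow] | np.ndarray,
    dup_multiplier: float = 3.0,
    del_multiplier: float = 2.0,
    max_n_fraction: float = 0.5,
    gc_bin_means: dict[int, float] | None = None,
) -> DepthCalibration:
    """Calibrate global mean/SD by a mode-centred Gaussian fit.

    A histogram of corrected depths (bin width max(1, range/200)) is built
    and a Gaussian is least-squares fitted to the bins whose centres lie
    within ±50% of the modal bin, so that duplicated/deleted tails do not
    bias the estimates.  On fit failure the calibration falls back to the
    median and 1.4826·MAD with a logged warning.
    """
    if isinstance(windows_or_depths, np.ndarray) or (
        len(windows_or_depths) and isinstance(windows_or_depths[0], (int, float, np.floating))
    ):
        depths = np.asarray(windows_or_depths, dtype=float)
    else:
        depths = np.array(
            [
                w.corrected_depth
                for w in windows_or_depths
                if w.usable(max_n_fraction) and w.corrected_depth is not None
            ],
            dtype=float,
        )
    if depths.size < 10:
        raise CalibrationError(f"only {depths.size} usable windows (need >= 10)")
    if depths.size < 500:
        log.warning("fit_gaussian: only %d usable windows (>= 500 recommended)", depths.size)

    mean, sd, method = _fit_mode_centred(depths)
    calib = DepthCalibration(
        mean=mean,
        sd=sd,
        dup_multiplier=dup_multiplier,
        del_multiplier=del_multiplier,
        gc_bin_means=gc_bin_means or {},
        fit_method=method,
    )
    return calib


def _fit_mode_centred(depths: np.ndarray) -> tuple[float, float, str]:
    rng = float(depths.max() - depths.min())
    if rng == 0.0:
        log.warning("fit_gaussian: degenerate (constant) depths; sd = 0")
        return float(depths[0]), 0.0, "degenerate"
    bin_width = max(1.0, rng / 200.0)
    nbins = max(3, int(math.ceil(rng / bin_width)))
    hist, edges = np.histogram(depths, bins=nbins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    mode_centre = centres[int(np.argmax(hist))]
    lo, hi = 0.5 * mode_centre, 1.5 * mode_centre
    sel = (centres >= lo) & (centres <= hi)
    if sel.sum() < 3:
        sel = np.ones_like(centres, dtype=bool)
    x, y = centres[sel], hist[sel].astype(float)
    core = depths[(depths >= lo) & (depths <= hi)]
    p0 = (float(y.max()), float(mode_centre), max(float(np.std(core)), bin_width / 2))
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=10000)
        a, mu, sigma = popt
        sigma = abs(float(sigma))
        if not (np.isfinite(mu) and np.isfinite(sigma)) or sigma == 0:
            raise RuntimeError("non-finite fit")
        return float(mu), sigma, "gaussian"
    except Exception:  # noqa: BLE001 - any optimizer failure takes the robust path
        med = float(np.median(depths))
        mad = float(np.median(np.abs(depths - med)))
        log.warning("fit_gaussian: mode-centred fit failed; falling back to median/MAD")
        return med, 1.4826 * mad, "median_mad"


def calibrate(
    windows: Sequence[DepthWindow],
    gc_bin_width: float = 0.01,
    min_bin_windows: int = 50,
    dup_multiplier: float = 3.0,
    del_multiplier: float = 2.0,
) -> DepthCalibration:
    """GC-correct then Gaussian-calibrate in one step (the usual entry point)."""
    interim = gc_correct(windows, gc_bin_width, min_bin_windows)
    return fit_gaussian(
        windows,
        dup_multiplier=dup_multiplier,
        del_multiplier=del_multiplier,
        gc_bin_means=interim.gc_bin_means,
    )
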
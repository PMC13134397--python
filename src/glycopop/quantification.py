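"""Chromatogram extraction and abundance quantification.

Extracted ion chromatograms (XICs) are pulled from runs at 10 ppm
mass accuracy: MS1 transitions from full scans, MS2 transitions from
every DIA window whose isolation range intersects the transition's
precursor range (feature superclass transitions have no single
precursor, so by default they draw on all windows, and areas measured
in multiple windows are summed).  Peak areas are trapezoidal after
subtraction of the in-window minimum as a local baseline.

Normalization follows the two conventions used downstream: division by
the sample's Y1 (peptide + HexNAc) area for feature quantification,
and percent-of-total per glycosylation site for glycoform abundance
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .feature_library import FeatureLibraryEntry, Transition
from .spectra_io import Run, Spectrum


@dataclass(frozen=True)
class ExtractionSettings:
    """Extraction parameters: 10 ppm accuracy, 3 MS1 isotopes."""

    ppm: float = 10.0
    n_isotopes: int = 3
    rt_window: Optional[Tuple[float, float]] = None  # minutes
    dda_id_gate: float = 5.0  # +/- minutes around an MS/MS ID for DDA MS1

    def __post_init__(self):
        if self.ppm <= 0:
            raise ValueError("ppm tolerance must be positive")


@dataclass
class XIC:
    """A chromatogram for one transition in one scan stream."""

    entry_id: str
    times: np.ndarray
    intensities: np.ndarray
    level: int
    window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("XIC times must be strictly increasing")

    @property
    def empty(self) -> bool:
        return self.times.size == 0

    @property
    def apex_time(self) -> Optional[float]:
        if self.empty or self.intensities.max() <= 0:
            return None
        return float(self.times[int(np.argmax(self.intensities))])


def _windows_for(
    run: Run, precursor_range: Optional[Tuple[float, float]]
) -> List[Tuple[float, float]]:
    if run.mode != "DIA":
        return []
    if precursor_range is None:
        return list(run.dia_windows)
    lo, hi = precursor_range
    return [w for w in run.dia_windows if w[0] <= hi and lo <= w[1]]


def extract_xic(
    run: Run,
    target_mz: float,
    level: int = 2,
    precursor_range: Optional[Tuple[float, float]] = None,
    settings: ExtractionSettings = ExtractionSettings(),
) -> List[XIC]:
    """Extract chromatograms for one target m/z.

    MS1 extraction (``level=1``) uses the full scans.  MS2 extraction
    returns one XIC per intersecting DIA window; callers sum their
    integrated areas.  Intensities are the summed peak intensities
    within the ppm tolerance per scan; an empty RT selection yields an
    empty XIC, not an error.
    """
    tol = target_mz * settings.ppm * 1e-6
    rt = settings.rt_window

    def series(scans: Sequence[Spectrum]) -> Tuple[np.ndarray, np.ndarray]:
        t, y = [], []
        for s in scans:
            if rt is not None and not (rt[0] <= s.retention_time <= rt[1]):
                continue
            t.append(s.retention_time)
            y.append(s.intensity_near(target_mz, tol))
        return np.array(t), np.array(y)

    if level == 1:
        t, y = series(run.ms1())
        return [XIC(entry_id=f"mz{target_mz:.4f}", times=t, intensities=y, level=1)]
    out = []
    if run.mode == "DIA":
        for w in _windows_for(run, precursor_range):
            scans = [
                s for s in run.ms2()
                if s.isolation_window is not None
                and abs(s.isolation_window[0] - w[0]) < 1e-6
                and abs(s.isolation_window[1] - w[1]) < 1e-6
            ]
            t, y = series(scans)
            out.append(XIC(entry_id=f"mz{target_mz:.4f}", times=t, intensities=y, level=2, window=w))
    else:
        if precursor_range is None:
            scans = run.ms2()
        else:
            lo, hi = precursor_range
            scans = [s for s in run.ms2() if lo <= s.precursor_mz <= hi]
        t, y = series(scans)
        out.append(XIC(entry_id=f"mz{target_mz:.4f}", times=t, intensities=y, level=2))
    return out


def integrate_peak(
    xic: XIC, rt_window: Optional[Tuple[float, float]] = None
) -> float:
    """Trapezoidal area over the RT window after local baseline subtraction.

    The baseline is the minimum intensity inside the window (a simple,
    monotone correction).  Empty XICs integrate to 0.
    """
    if xic.empty:
        return 0.0
    t, y = xic.times, xic.intensities
    if rt_window is not None:
        mask = (t >= rt_window[0]) & (t <= rt_window[1])
        t, y = t[mask], y[mask]
    if t.size == 0:
        return 0.0
    if t.size == 1:
        return float(max(y[0], 0.0))
    baseline = y.min()
    return float(np.trapezoid(y - baseline, t))


def quantify_transition(
    run: Run,
    transition: Transition,
    settings: ExtractionSettings = ExtractionSettings(),
    rt_window: Optional[Tuple[float, float]] = None,
    precursor_range: Optional[Tuple[float, float]] = None,
) -> float:
    """Integrated area of one transition; multi-window areas are summed."""
    level = 1 if transition.kind == "precursor-isotope" else 2
    if precursor_range is None and level == 2:
        w = 1.5  # narrow range around the precursor for glycoform-specific MS2
        precursor_range = (transition.precursor_mz - w, transition.precursor_mz + w)
    xics = extract_xic(run, transition.product_mz, level, precursor_range, settings)
    return sum(integrate_peak(x, rt_window) for x in xics)


def quantify_feature(
    run: Run,
    entry: FeatureLibraryEntry,
    settings: ExtractionSettings = ExtractionSettings(),
    rt_window: Optional[Tuple[float, float]] = None,
    specific_only: bool = True,
) -> float:
    """Summed area of a feature superclass entry across all DIA windows.

    Feature transitions come from many precursors across the isolation
    range, so every DIA window contributes; only feature-specific
    transitions are used unless ``specific_only`` is False.
    """
    transitions = entry.specific_transitions() if specific_only else entry.transitions
    total = 0.0
    for t in transitions:
        xics = extract_xic(run, t.product_mz, 2, None, settings)
        total += sum(integrate_peak(x, rt_window) for x in xics)
    return total


def normalize_to_y1(
    areas: pd.DataFrame, y1_areas: Mapping[str, float]
) -> pd.DataFrame:
    """Divide each sample column by that sample's Y1 area.

    Samples with a non-positive Y1 area are flagged (set to NaN) rather
    than silently scaled.
    """
    out = areas.astype(float).copy()
    flagged = []
    for sample in out.columns:
        y1 = float(y1_areas.get(sample, 0.0))
        if y1 > 0:
            out[sample] = out[sample] / y1
        else:
            out[sample] = np.nan
            flagged.append(sample)
    out.attrs["flagged_samples"] = flagged
    return out


def percent_of_total(areas: pd.DataFrame, site: Optional[pd.Series] = None) -> pd.DataFrame:
    """Express areas as percent of the per-site total per sample.

    ``site`` maps each row to its glycosylation site; without it all
    rows share one site.  Missing values (NaN) are excluded from the
    denominators and stay missing.  Columns whose site total is zero
    are flagged via ``attrs['missing']`` and left as NaN.
    """
    out = areas.astype(float).copy()
    groups = site if site is not None else pd.Series("site", index=areas.index)
    missing = []
    for site_name, idx in groups.groupby(groups).groups.items():
        block = out.loc[idx]
        totals = block.sum(axis=0, skipna=True)
        for sample in out.columns:
            if totals[sample] > 0:
                out.loc[idx, sample] = block[sample] * 100.0 / totals[sample]
            else:
                out.loc[idx, sample] = np.nan
                missing.append((site_name, sample))
    out.attrs["normalization"] = "percent_of_total"
    out.attrs["missing"] = missing
    return out


def compare_groups(
    matrix: pd.DataFrame, groups: Mapping[str, str], reference: Optional[str] = None
) -> pd.DataFrame:
    """Per-row Welch test on log2 values with Benjamini-Hochberg control.

    ``groups`` maps sample (column) names to exactly two group labels;
    ``reference`` names the denominator group for the log-ratio
    (defaults to the alphabetically first).  Rows that are constant or
    lack >=2 finite values per group get NaN statistics and the
    ``undefined`` flag.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    ref = reference if reference is not None else labels[0]
    other = [g for g in labels if g != ref][0]
    cols_ref = [c for c in matrix.columns if groups.get(c) == ref]
    cols_other = [c for c in matrix.columns if groups.get(c) == other]
    if len(cols_ref) < 2 or len(cols_other) < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(matrix[cols_ref + cols_other].astype(float))
    rows = []
    for name, row in log2.iterrows():
        a = row[cols_other].dropna().to_numpy()
        b = row[cols_ref].dropna().to_numpy()
        undefined = (
            a.size < 2 or b.size < 2
            or not np.isfinite(a).all() or not np.isfinite(b).all()
            or (np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean())
        )
        if undefined and not (a.size >= 2 and b.size >= 2 and np.isfinite(a).all() and np.isfinite(b).all()):
            rows.append({"row": name, "log2_ratio": np.nan, "t": np.nan, "p": np.nan, "undefined": True})
            continue
        ratio = a.mean() - b.mean()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # no within-group variance: statistic undefined
            rows.append({"row": name, "log2_ratio": ratio, "t": np.nan, "p": np.nan, "undefined": True})
            continue
        t, p = _stats.ttest_ind(a, b, equal_var=False)
        rows.append({"row": name, "log2_ratio": ratio, "t": float(t), "p": float(p), "undefined": False})
    df = pd.DataFrame(rows).set_index("row")
    mask = df["p"].notna()
    df["p_adj"] = np.nan
    if mask.any():
        df.loc[mask, "p_adj"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df
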
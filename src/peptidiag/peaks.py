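"""Peak detection, matrix-cluster exclusion, cross-sample alignment and
feature-matrix construction, plus the two-group differential screen.

Detection is noise-adaptive: a point is a peak apex when it is a local
maximum whose height exceeds ``snr_min`` times a robust local noise level
(1.4826 x the sliding-window median absolute deviation).  Detected peaks
are aligned across samples by an iterative greedy algorithm at a relative
tolerance (default 2,500 ppm), yielding consensus m/z bins; the sample x bin
matrix of relative peak areas is the feature table for all downstream
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .spectra import Spectrum

__all__ = [
    "Peak",
    "PeakList",
    "FeatureBin",
    "FeatureMatrix",
    "estimate_noise",
    "detect_peaks",
    "filter_matrix_clusters",
    "align_peaks",
    "build_feature_matrix",
    "differential_screen",
    "DifferentialTable",
]

MATRIX_REGION = (1500.0, 2000.0)


@dataclass
class Peak:
    mz: float
    area: float
    snr: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.area < 0 or self.snr < 0:
            raise ValueError("peak area and SNR must be non-negative")


@dataclass
class PeakList:
    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


@dataclass
class FeatureBin:
    consensus_mz: float
    members: list[tuple[str, Peak]]
    support: float = 0.0


def estimate_noise(s: Spectrum, window_da: float = 200.0) -> np.ndarray:
    """Per-point robust noise level from a sliding window.

    The estimator is the rolling quantile spread q(0.8413) - q(0.5), which
    equals one standard deviation for Gaussian noise — the same population
    quantity as 1.4826 x MAD — but, unlike the MAD, is unbiased when the
    noise has been clipped at zero by baseline subtraction (clipping only
    displaces quantiles below the median).  Rolling quantiles are evaluated
    on anchor points every quarter-window and linearly interpolated, which
    matches the dense estimate at the smoothness of real noise floors.  A
    window wider than the spectrum degrades to a single global estimate.
    """
    _, spread = _floor_and_noise(s, window_da)
    return spread


def _floor_and_noise(s: Spectrum, window_da: float) -> tuple[np.ndarray, np.ndarray]:
    """Rolling median floor and one-sigma quantile spread (see
    :func:`estimate_noise`)."""
    step = float(np.median(np.diff(s.mz))) if len(s) > 1 else 1.0
    if window_da <= step:
        raise ValueError("noise window must exceed the grid step")
    y = s.intensity
    n = len(y)
    w = int(round(window_da / step))
    q_hi = 0.84134  # one-sigma upper quantile of a Gaussian
    if w >= n:
        med = float(np.median(y))
        spread = max(float(np.quantile(y, q_hi)) - med, 0.0)
        return np.full(n, med), np.full(n, spread)
    stride = max(w // 4, 1)
    roll = pd.Series(y).rolling(w, center=True, min_periods=1, step=stride)
    hi = roll.quantile(q_hi)
    med = roll.quantile(0.5)
    anchors = hi.index.to_numpy()
    pts = np.arange(n)
    floor = np.interp(pts, anchors, med.to_numpy())
    spread = np.interp(pts, anchors, np.clip(hi.to_numpy() - med.to_numpy(), 0.0, None))
    return floor, spread


def detect_peaks(
    s: Spectrum,
    snr_min: float = 3.0,
    window_da: float = 200.0,
    noise_floor: float = 1e-12,
) -> PeakList:
    """Noise-adaptive peak picking on a preprocessed spectrum.

    Peak height is measured above the rolling-median local floor, which makes
    detection and quantification insensitive to any residual background left
    by baseline correction.  Local maxima whose floor-relative height exceeds
    ``snr_min`` x local noise are kept; the centroid is the height-weighted
    mean m/z over the half-height support and the area the trapezoidal
    integral of the floor-relative height over that support.  Apexes closer
    than one grid step are merged (highest wins).
    """
    mz = s.mz
    if not np.any(s.intensity > 0):
        return PeakList(sample_id=s.sample_id, peaks=[])
    floor, spread = _floor_and_noise(s, window_da)
    noise = np.maximum(spread, noise_floor)
    y = np.clip(s.intensity - floor, 0.0, None)
    idx, _ = find_peaks(y, height=snr_min * noise)
    peaks: list[Peak] = []
    last_apex = -2
    for i in idx:
        if i - last_apex <= 1 and peaks:
            if y[i] > y[last_apex]:
                peaks.pop()
            else:
                continue
        half = y[i] / 2.0
        lo = i
        while lo > 0 and half <= y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < len(y) - 1 and half <= y[hi + 1] <= y[hi]:
            hi += 1
        seg = slice(lo, hi + 1)
        wsum = y[seg].sum()
        centroid = float((mz[seg] * y[seg]).sum() / wsum) if wsum > 0 else float(mz[i])
        area = float(np.trapezoid(y[seg], mz[seg])) if hi > lo else float(y[i]) * float(
            np.median(np.diff(mz))
        )
        peaks.append(
            Peak(mz=centroid, area=area, snr=float(y[i] / noise[i]), sample_id=s.sample_id)
        )
        last_apex = i
    return PeakList(sample_id=s.sample_id, peaks=peaks)


def filter_matrix_clusters(
    pl: PeakList, artifact_mzs, tol_ppm: float = 2500.0
) -> PeakList:
    """Drop peaks that are BOTH inside the 1,500-2,000 Da matrix-cluster
    region AND within ``tol_ppm`` of a listed artifact m/z.  Genuine peptide
    peaks inside the region (no artifact match) are retained."""
    artifact_mzs = np.asarray(list(artifact_mzs), dtype=float)
    if artifact_mzs.size == 0:
        return pl
    kept = []
    for p in pl.peaks:
        if MATRIX_REGION[0] <= p.mz <= MATRIX_REGION[1]:
            if np.any(np.abs(artifact_mzs - p.mz) / p.mz * 1e6 <= tol_ppm):
                continue
        kept.append(p)
    return PeakList(sample_id=pl.sample_id, peaks=kept)


def align_peaks(
    peaklists: list[PeakList],
    tol_ppm: float = 2500.0,
    max_iter: int = 10,
    min_support: float = 0.0,
) -> list[FeatureBin]:
    """Iterative greedy cross-sample peak alignment.

    All peaks are pooled; seeds are taken in descending order of a
    support-weighted intensity score (peak area x number of pooled peaks
    within tolerance, ties broken by lower m/z).  Each seed collects, per
    sample, the nearest unassigned peak within ``tol_ppm`` of the running
    consensus (intensity-weighted mean of member m/z); membership is
    re-evaluated against the updated consensus until stable or ``max_iter``
    passes.  Every returned member is within ``tol_ppm`` of the final
    consensus.  Bins supported by fewer than ``min_support`` of the samples
    are dropped.
    """
    n_samples = len(peaklists)
    all_mz, all_area, all_sample = [], [], []
    for si, pl in enumerate(peaklists):
        for p in pl.peaks:
            all_mz.append(p.mz)
            all_area.append(p.area)
            all_sample.append(si)
    if not all_mz:
        return []
    mz = np.asarray(all_mz)
    area = np.asarray(all_area)
    sample = np.asarray(all_sample)
    order = np.argsort(mz, kind="stable")
    mz, area, sample = mz[order], area[order], sample[order]
    peak_ref = [peaklists[s].peaks[0] for s in sample]  # placeholder, fixed below
    # map sorted position -> actual Peak object
    flat_peaks = [p for pl in peaklists for p in pl.peaks]
    peak_ref = [flat_peaks[i] for i in order]

    n = len(mz)
    lo_idx = np.searchsorted(mz, mz * (1 - tol_ppm * 1e-6), side="left")
    hi_idx = np.searchsorted(mz, mz * (1 + tol_ppm * 1e-6), side="right")
    support_count = hi_idx - lo_idx
    score = area * support_count
    seed_order = np.lexsort((mz, -score))

    assigned = np.full(n, False)
    bins: list[FeatureBin] = []
    for seed in seed_order:
        if assigned[seed]:
            continue
        consensus = mz[seed]
        members: dict[int, int] = {}
        for _ in range(max_iter):
            lo = np.searchsorted(mz, consensus * (1 - tol_ppm * 1e-6), side="left")
            hi = np.searchsorted(mz, consensus * (1 + tol_ppm * 1e-6), side="right")
            cand = [
                j for j in range(lo, hi)
                if (not assigned[j]) or j in members.values()
            ]
            new_members: dict[int, int] = {}
            for j in cand:
                sj = sample[j]
                if sj in new_members:
                    if abs(mz[j] - consensus) < abs(mz[new_members[sj]] - consensus):
                        new_members[sj] = j
                else:
                    new_members[sj] = j
            if not new_members:
                break
            idxs = np.fromiter(new_members.values(), dtype=int)
            consensus = float((mz[idxs] * area[idxs]).sum() / area[idxs].sum())
            if new_members == members:
                break
            members = new_members
        if not members:
            members = {int(sample[seed]): int(seed)}
            consensus = float(mz[seed])
        # hard tolerance guarantee against the final consensus
        members = {
            s_: j for s_, j in members.items()
            if abs(mz[j] - consensus) / consensus * 1e6 <= tol_ppm
        }
        if not members:
            continue
        for j in members.values():
            assigned[j] = True
        bins.append(
            FeatureBin(
                consensus_mz=consensus,
                members=[(peaklists[s_].sample_id, peak_ref[j]) for s_, j in sorted(members.items())],
                support=len(members) / max(n_samples, 1),
            )
        )
    bins = [b for b in bins if b.support >= min_support]
    bins.sort(key=lambda b: b.consensus_mz)
    return bins


@dataclass
class FeatureMatrix:
    """Samples x aligned-peak matrix of relative areas, plus labels.

    ``values`` is a DataFrame indexed by sample_id with float consensus-m/z
    column labels; ``fill_mask`` marks imputed cells; ``labels`` is a Series
    of "TC"/"HC" aligned with the rows (may be empty for unlabelled data).
    """

    values: pd.DataFrame
    labels: pd.Series
    fill_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("feature matrix contains negative areas")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def bin_mzs(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def restrict(self, mzs) -> "FeatureMatrix":
        """Column subset by exact consensus m/z values."""
        cols = []
        for m in mzs:
            matches = [c for c in self.values.columns if np.isclose(float(c), float(m))]
            if not matches:
                raise KeyError(f"feature m/z {m} not in matrix")
            cols.append(matches[0])
        return FeatureMatrix(
            values=self.values[cols].copy(),
            labels=self.labels.copy(),
            fill_mask=self.fill_mask[cols].copy(),
        )


def build_feature_matrix(
    bins: list[FeatureBin],
    sample_ids: list[str],
    fill: str = "zero",
    labels=None,
) -> FeatureMatrix:
    """Assemble the samples x bins relative-area matrix.

    Missing cells are filled per policy: ``zero`` writes 0; ``interpolate``
    writes the mean of the same sample's areas in the nearest flanking
    non-missing bins (0 at the edges).  ``fill_mask`` records every imputed
    cell.
    """
    if fill not in ("zero", "interpolate"):
        raise ValueError(f"unknown fill policy {fill!r}")
    cols = [b.consensus_mz for b in bins]
    mat = np.full((len(sample_ids), len(bins)), np.nan)
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    for j, b in enumerate(bins):
        seen = set()
        for sid, peak in b.members:
            if sid in seen:
                raise ValueError(
                    f"bin at m/z {b.consensus_mz:.2f} has duplicate sample {sid!r}"
                )
            seen.add(sid)
            if sid in row_of:
                mat[row_of[sid], j] = peak.area
    mask = np.isnan(mat)
    if fill == "zero":
        filled = np.where(mask, 0.0, mat)
    else:
        filled = mat.copy()
        for i in range(len(sample_ids)):
            present = np.where(~mask[i])[0]
            for j in np.where(mask[i])[0]:
                left = present[present < j]
                right = present[present > j]
                if left.size and right.size:
                    filled[i, j] = 0.5 * (mat[i, left[-1]] + mat[i, right[0]])
                else:
                    filled[i, j] = 0.0
    values = pd.DataFrame(filled, index=list(sample_ids), columns=cols)
    lab = (
        pd.Series(list(labels), index=list(sample_ids))
        if labels is not None
        else pd.Series([], dtype=object)
    )
    return FeatureMatrix(
        values=values,
        labels=lab,
        fill_mask=pd.DataFrame(mask, index=list(sample_ids), columns=cols),
    )


@dataclass
class DifferentialTable:
    """Per-bin two-group screen: log2FC, p and BH-adjusted q."""

    table: pd.DataFrame  # columns: mz, log2fc, p_value, q_value

    def top_k_by_abs_log2fc(self, k: int) -> pd.DataFrame:
        return self.table.reindex(
            self.table.log2fc.abs().sort_values(ascending=False).index
        ).head(k)

    def top_k_by_p(self, k: int) -> pd.DataFrame:
        return self.table.sort_values("p_value").head(k)


def differential_screen(m: FeatureMatrix, test: str = "welch") -> DifferentialTable:
    """Bin-wise TC-vs-HC screen.

    log2FC uses a scale-invariant pseudocount (1e-6 x grand mean); p-values
    come from Welch's t on log-areas (or Mann-Whitney by request) and are
    BH-adjusted.
    """
    if m.labels.empty:
        raise ValueError("feature matrix carries no labels")
    y = m.labels.to_numpy()
    tc = m.values.to_numpy()[y == "TC"]
    hc = m.values.to_numpy()[y == "HC"]
    if tc.shape[0] < 2 or hc.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples")
    eps = 1e-6 * max(float(m.values.to_numpy().mean()), np.finfo(float).tiny)
    log2fc = np.log2((tc.mean(axis=0) + eps) / (hc.mean(axis=0) + eps))
    if test == "welch":
        _, p = ttest_ind(
            np.log2(tc + eps), np.log2(hc + eps), axis=0, equal_var=False
        )
    elif test == "mannwhitney":
        p = np.array(
            [mannwhitneyu(tc[:, j], hc[:, j]).pvalue for j in range(tc.shape[1])]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(np.isfinite(p), p, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return DifferentialTable(
        pd.DataFrame(
            {"mz": m.bin_mzs, "log2fc": log2fc, "p_value": p, "q_value": q}
        )
    )
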
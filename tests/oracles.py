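"""Independent brute-force reference implementations used to validate the
package's algorithms on small instances.  These deliberately share no code
with the implementations they check."""

from __future__ import annotations

import numpy as np

from peptidiag.peaks import Peak, PeakList


def exhaustive_align(peaklists: list[PeakList], tol_ppm: float):
    """Exhaustive minimal-bin partition of pooled peaks.

    Searches all set partitions (branch-and-bound) subject to: at most one
    peak per sample per bin, and every member within ``tol_ppm`` of the
    bin's intensity-weighted consensus m/z.  Minimizes bin count, breaking
    ties by total centroid dispersion sum(|mz - consensus|).  Returns the
    optimal partition as a sorted tuple of frozensets of (sample, mz) pairs.
    """
    peaks = [
        (pl.sample_id, p.mz, p.area) for pl in peaklists for p in pl.peaks
    ]
    peaks.sort(key=lambda t: t[1])
    n = len(peaks)
    best = {"count": np.inf, "disp": np.inf, "bins": None}

    def consensus_ok(idxs) -> tuple[bool, float]:
        mz = np.array([peaks[i][1] for i in idxs])
        ar = np.array([peaks[i][2] for i in idxs])
        c = (mz * ar).sum() / ar.sum()
        ok = np.all(np.abs(mz - c) / c * 1e6 <= tol_ppm)
        return bool(ok), float(np.abs(mz - c).sum())

    def recurse(i: int, bins: list[list[int]]):
        if len(bins) > best["count"]:
            return
        if i == n:
            disp = 0.0
            for b in bins:
                ok, d = consensus_ok(b)
                if not ok:
                    return
                disp += d
            key = (len(bins), disp)
            if key < (best["count"], best["disp"]):
                best.update(count=len(bins), disp=disp,
                            bins=[tuple(b) for b in bins])
            return
        sid, mz, _ = peaks[i]
        for b in bins:
            if any(peaks[j][0] == sid for j in b):
                continue
            # necessary condition: pairwise within 2 tol of each other
            if any(abs(peaks[j][1] - mz) / mz * 1e6 > 2 * tol_ppm for j in b):
                continue
            b.append(i)
            recurse(i + 1, bins)
            b.pop()
        bins.append([i])
        recurse(i + 1, bins)
        bins.pop()

    recurse(0, [])
    assert best["bins"] is not None
    return tuple(
        sorted(
            frozenset((peaks[i][0], peaks[i][1]) for i in b)
            for b in best["bins"]
        )
    )


def random_alignment_instance(seed: int, tol_ppm: float = 2500.0):
    """A clustered random instance with <= 12 peaks over 3 samples: cluster
    centres many tolerances apart, members within a third of the tolerance,
    at most one peak per sample per cluster."""
    rng = np.random.default_rng(seed)
    n_clusters = rng.integers(2, 5)
    centres = np.sort(rng.uniform(1500, 9000, n_clusters))
    while np.any(np.diff(centres) / centres[:-1] < 6 * tol_ppm * 1e-6):
        centres = np.sort(rng.uniform(1500, 9000, n_clusters))
    sample_ids = ["A", "B", "C"]
    per_sample: dict[str, list[Peak]] = {s: [] for s in sample_ids}
    total = 0
    for c in centres:
        members = rng.choice(3, rng.integers(1, 4), replace=False)
        for m in members:
            if total >= 12:
                break
            mz = c * (1 + rng.uniform(-tol_ppm / 3, tol_ppm / 3) * 1e-6)
            per_sample[sample_ids[m]].append(
                Peak(mz=float(mz), area=float(rng.uniform(10, 100)),
                     snr=10.0, sample_id=sample_ids[m])
            )
            total += 1
    return [PeakList(sample_id=s, peaks=per_sample[s]) for s in sample_ids]


def bins_as_sets(bins):
    """Canonical form of FeatureBin output for comparison with the oracle."""
    return tuple(
        sorted(
            frozenset((sid, p.mz) for sid, p in b.members) for b in bins
        )
    )
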
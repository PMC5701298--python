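"""Copy-number profiling from binned read depths.

Normalization against a matched control, integer copy-number inference by a
Gaussian-emission HMM, MAPD quality control, per-bin median consensus profiles
and pairwise profile similarity — for single cells and bulk regions alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BinGrid

__all__ = [
    "PipelineParams",
    "CopyNumberProfile",
    "normalize_depth",
    "infer_copy_number",
    "mapd",
    "qc_filter",
    "consensus_profile",
    "profile_similarity",
]

# MAPD of iid Gaussian noise: median|N(0, 2*sigma^2)| = sigma * sqrt(2) * PHI_INV_75
PHI_INV_75 = 0.6744897501960817


@dataclass
class PipelineParams:
    """Knobs for the depth -> copy-number pipeline."""

    mapd_threshold: float = 0.25
    bin_size: int = 500_000
    max_cn: int = 8
    hmm_transition_stay: float = 0.995
    min_control_count: int = 10
    emission_sigma_floor: float = 0.05
    emission_sigma: float | None = None  # fixed sigma; None = estimate from data
    gc_correction: bool = False  # hook only; disabled by default

    def __post_init__(self):
        if self.mapd_threshold <= 0:
            raise ValueError("mapd_threshold must be > 0")
        if self.max_cn < 2:
            raise ValueError("max_cn must be >= 2")
        if not 0 < self.hmm_transition_stay < 1:
            raise ValueError("hmm_transition_stay must be in (0, 1)")


@dataclass
class CopyNumberProfile:
    """Per-bin normalized depth ratio (1.0 = diploid) and inferred copy number."""

    sample_id: str
    grid: BinGrid
    ratio: np.ndarray
    log2_ratio: np.ndarray
    mask: np.ndarray  # True = bin usable
    cn_state: np.ndarray | None = None
    mapd: float | None = None

    def __post_init__(self):
        n = len(self.grid)
        for name in ("ratio", "log2_ratio", "mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} not aligned to grid ({n} bins)")

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["ratio"] = self.ratio
        df["log2_ratio"] = self.log2_ratio
        df["masked"] = ~self.mask
        if self.cn_state is not None:
            df["cn_state"] = self.cn_state
        return df


def normalize_depth(
    raw: np.ndarray,
    control: np.ndarray,
    grid: BinGrid,
    params: PipelineParams | None = None,
    sample_id: str = "sample",
) -> CopyNumberProfile:
    """Control-normalize binned counts into a ratio profile.

    ratio_b = (raw_b / sum raw) / (control_b / sum control), rescaled so the
    median autosomal unmasked ratio is 1.0. Bins whose control count falls
    below ``min_control_count`` are masked.
    """
    params = params or PipelineParams()
    raw = np.asarray(raw, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(raw) != len(grid) or len(control) != len(grid):
        raise ValueError("raw/control not aligned to grid")
    if raw.sum() <= 0:
        raise ValueError("raw counts are all zero")
    mask = control >= params.min_control_count
    if mask.mean() < 0.95:
        warnings.warn(
            f"control below min_control_count in {(~mask).mean():.1%} of bins", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (raw / raw.sum()) / (control / control.sum())
    ratio[~mask] = np.nan
    auto = mask & grid.autosomal
    med = np.nanmedian(ratio[auto]) if auto.any() else np.nanmedian(ratio[mask])
    if not np.isfinite(med) or med <= 0:
        raise ValueError("cannot rescale: median ratio is not positive")
    ratio = ratio / med
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(ratio)
    mask = mask & np.isfinite(log2_ratio)
    return CopyNumberProfile(sample_id, grid, ratio, log2_ratio, mask)


def _viterbi(obs: np.ndarray, means: np.ndarray, sigma: float, stay: float) -> np.ndarray:
    """Viterbi path for Gaussian emissions with a stay/uniform-switch transition."""
    n, k = len(obs), len(means)
    loglik = -0.5 * ((obs[:, None] - means[None, :]) / sigma) ** 2
    log_stay = np.log(stay)
    log_switch = np.log((1.0 - stay) / (k - 1))
    trans = np.full((k, k), log_switch)
    np.fill_diagonal(trans, log_stay)
    score = loglik[0].copy()
    back = np.zeros((n, k), dtype=np.intp)
    for t in range(1, n):
        cand = score[:, None] + trans
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(k)] + loglik[t]
    path = np.empty(n, dtype=np.intp)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _fill_nearest(states: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid positions with the nearest valid state (ties -> left)."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return states
    pos = np.arange(len(states))
    nearest = idx[np.argmin(np.abs(pos[:, None] - idx[None, :]), axis=1)]
    out = states.copy()
    out[~valid] = states[nearest[~valid]]
    return out


def infer_copy_number(
    profile: CopyNumberProfile, params: PipelineParams | None = None
) -> CopyNumberProfile:
    """Fill ``cn_state`` with the Viterbi path over integer states 0..max_cn.

    Emissions are Gaussian on the ratio scale, centered at state/2, with a
    shared sigma estimated from consecutive-bin residuals. The HMM runs per
    chromosome over unmasked bins; masked bins inherit the nearest unmasked
    state.
    """
    params = params or PipelineParams()
    if len(profile.ratio) == 0:
        raise ValueError("empty profile")
    means = np.arange(params.max_cn + 1) / 2.0
    ratio = profile.ratio
    mask = profile.mask
    # noise scale from within-segment consecutive differences (robust to true CN steps)
    diffs = []
    for sl in profile.grid.chrom_slices().values():
        r, m = ratio[sl], mask[sl]
        d = np.diff(r[m])
        if d.size:
            diffs.append(d)
    if params.emission_sigma is not None:
        sigma = params.emission_sigma
    else:
        sigma = params.emission_sigma_floor
        if diffs:
            d = np.abs(np.concatenate(diffs))
            if d.size:
                sigma = max(sigma, float(np.median(d)) / (np.sqrt(2.0) * PHI_INV_75))
    states = np.zeros(len(ratio), dtype=np.intp)
    for sl in profile.grid.chrom_slices().values():
        m = mask[sl]
        sub = np.zeros(sl.stop - sl.start, dtype=np.intp)
        if m.any():
            path = _viterbi(ratio[sl][m], means, sigma, params.hmm_transition_stay)
            sub[m] = path
            sub = _fill_nearest(sub, m)
        else:
            sub[:] = 2
        states[sl] = sub
    profile.cn_state = states.astype(np.int64)
    return profile


def mapd(profile: CopyNumberProfile) -> float:
    """Median absolute difference between consecutive unmasked bins' log2 ratios.

    Differences are taken within chromosomes only; the result is stored on the
    profile and returned.
    """
    diffs = []
    for sl in profile.grid.chrom_slices().values():
        x = profile.log2_ratio[sl][profile.mask[sl]]
        if x.size >= 2:
            diffs.append(np.diff(x))
    if not diffs:
        raise ValueError("need >= 2 unmasked bins on some chromosome")
    value = float(np.median(np.abs(np.concatenate(diffs))))
    profile.mapd = value
    return value


def qc_filter(
    cells: list[CopyNumberProfile], params: PipelineParams | None = None
) -> tuple[list[CopyNumberProfile], list[CopyNumberProfile]]:
    """Partition cells into (pass, fail) by strict ``mapd < mapd_threshold``."""
    params = params or PipelineParams()
    passed, failed = [], []
    for cell in cells:
        value = cell.mapd if cell.mapd is not None else mapd(cell)
        (passed if value < params.mapd_threshold else failed).append(cell)
    return passed, failed


def consensus_profile(
    cells: list[CopyNumberProfile], sample_id: str = "consensus"
) -> CopyNumberProfile:
    """Per-bin median of integer copy-number states (even counts -> lower median)."""
    if not cells:
        raise ValueError("empty cell set")
    grid = cells[0].grid
    for c in cells[1:]:
        if c.grid != grid:
            raise ValueError("cells are not on a shared grid")
    states = np.stack([c.cn_state for c in cells])
    if any(c.cn_state is None for c in cells):
        raise ValueError("all cells need cn_state (run infer_copy_number)")
    # lower median keeps the consensus integer-valued for even cell counts
    cons = np.sort(states, axis=0)[(len(cells) - 1) // 2]
    ratio = cons / 2.0
    with np.errstate(divide="ignore"):
        log2r = np.log2(ratio)
    mask = np.logical_and.reduce([c.mask for c in cells])
    return CopyNumberProfile(sample_id, grid, ratio, log2r, mask, cn_state=cons)


def profile_similarity(profiles: list[CopyNumberProfile]) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlation of ratio profiles over commonly unmasked bins.

    Returns the symmetric matrix (diagonal 1) and the mean over the off-diagonal
    upper triangle. Constant profiles yield NaN rows/columns with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    grid = profiles[0].grid
    if any(p.grid != grid for p in profiles):
        raise ValueError("profiles are not on a shared grid")
    common = np.logical_and.reduce([p.mask for p in profiles])
    if common.sum() < 2:
        raise ValueError("fewer than 2 commonly unmasked bins")
    data = np.stack([p.ratio[common] for p in profiles])
    sd = data.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn("constant profile(s): correlation undefined, masked as NaN", stacklevel=2)
    with np.errstate(invalid="ignore"):
        mat = np.corrcoef(data)
    mat[const, :] = np.nan
    mat[:, const] = np.nan
    np.fill_diagonal(mat, 1.0)
    iu = np.triu_indices(len(profiles), k=1)
    upper = mat[iu]
    mean = float(np.nanmean(upper)) if np.isfinite(upper).any() else float("nan")
    return mat, mean
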
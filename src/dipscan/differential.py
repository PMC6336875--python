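"""Differential permissibility analysis.

Profiles from different inserted domains are compared three ways: dataset /
position Pearson correlation matrices with average-linkage clustering
(NA treated as 0, so undersampled positions do not delete whole rows),
site-level differential calls (Hamming criterion on binarized profiles,
Euclidean distance on z-scores), and a window-15 moving average of the
z-score difference whose >1 SD excursions define differentially permissible
regions. Site-set contrasts use the unpaired Wilcoxon rank-sum test, and
z-scores can be exported into the B-factor column of a PDB file for
structure mapping.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class CorrelationMatrix:
    labels: list[str]
    matrix: np.ndarray
    cluster_order: np.ndarray


@dataclass
class DifferentialCallSet:
    """Per-slot differential flags; NA where either input is NA."""

    flags: np.ndarray  # object array of 'differential' / 'concordant' / None
    n_diff: int
    n_compared: int

    @property
    def percent(self) -> str:
        """Differential share of compared sites, round-half-up integer."""
        if self.n_compared == 0:
            return "0%"
        pct = decimal.Decimal(100 * self.n_diff) / decimal.Decimal(self.n_compared)
        return f"{pct.quantize(decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP)}%"

    def differential_mask(self) -> np.ndarray:
        return np.array([f == "differential" for f in self.flags])


@dataclass
class SmoothedDifference:
    smoothed: np.ndarray
    sd_threshold: float
    regions: list[tuple[int, int]]  # half-open slot intervals
    window: int
    degenerate: bool = False


def _values(profile) -> np.ndarray:
    return np.asarray(getattr(profile, "values", profile), dtype=float)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(profiles: Mapping[str, object] | Sequence,
                       axis: Literal["dataset", "position"] = "dataset",
                       method: Literal["pearson", "spearman"] = "pearson",
                       na_policy: Literal["zero", "complete"] = "zero",
                       ) -> CorrelationMatrix:
    """Pairwise correlation matrix over datasets or positions.

    ``profiles`` maps labels to equal-length value vectors (profile objects
    or arrays). Under ``na_policy='zero'`` NAs are replaced by 0 before
    correlating; ``'complete'`` uses pairwise-complete observations.
    Average-linkage hierarchical clustering on 1 - r gives ``cluster_order``.
    Constant vectors yield NA correlations with a warning.
    """
    import pandas as pd

    if isinstance(profiles, Mapping):
        data = {str(k): _values(v) for k, v in profiles.items()}
    else:
        data = {f"d{i}": _values(v) for i, v in enumerate(profiles)}
    if len(data) < 2 and axis == "dataset":
        raise ValueError("need at least two datasets")
    df = pd.DataFrame(data)
    if axis == "position":
        df = df.T
        df.columns = [str(c) for c in df.columns]
    if na_policy == "zero":
        df = df.fillna(0.0)
    labels = list(df.columns)
    constant = [c for c in labels if df[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"constant vectors, correlations set to NA: {constant}",
                      RuntimeWarning, stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = df.corr(method=method, min_periods=3).to_numpy()
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist[~np.isfinite(dist)] = 2.0
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    order = hierarchy.leaves_list(
        hierarchy.linkage(squareform(dist, checks=False), method="average"))
    return CorrelationMatrix(labels, corr, np.asarray(order))


def property_correlation(mean_profiles: Mapping[str, object], features,
                         method: str = "spearman",
                         min_positions: int = 3):
    """Spearman rho of each domain's mean permissibility against each protein
    property, over positions non-NA in both (average ranks on ties).
    ``features`` is a FeatureTable or DataFrame indexed by insertion slot.
    Returns a DataFrame (domains x features).
    """
    import pandas as pd

    table = features.values if hasattr(features, "categories") else features
    out = {}
    for domain, prof in mean_profiles.items():
        v = _values(prof)
        slots = np.asarray(table.index)
        valid_slots = slots[(slots >= 0) & (slots < len(v))]
        pv = v[valid_slots]
        row = {}
        for feat in table.columns:
            fv = table.loc[valid_slots, feat].to_numpy(float)
            ok = ~np.isnan(pv) & ~np.isnan(fv)
            if ok.sum() < min_positions:
                raise ValueError(
                    f"fewer than {min_positions} aligned positions for "
                    f"{domain}/{feat}")
            if method == "spearman":
                rho = stats.spearmanr(pv[ok], fv[ok]).statistic
            else:
                rho = stats.pearsonr(pv[ok], fv[ok]).statistic
            row[feat] = rho
        out[domain] = row
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# site-level differential metrics
# ---------------------------------------------------------------------------

def hamming_differential(bin_a, bin_b) -> DifferentialCallSet:
    """Differential sites as bit disagreement (XOR) of two binarized
    profiles over jointly non-NA positions."""
    a, b = _values(bin_a), _values(bin_b)
    if len(a) != len(b):
        raise ValueError("profiles must have the same length")
    both = ~np.isnan(a) & ~np.isnan(b)
    flags = np.empty(len(a), dtype=object)
    flags[:] = None
    flags[both & (a != b)] = "differential"
    flags[both & (a == b)] = "concordant"
    return DifferentialCallSet(flags, int(np.sum(both & (a != b))),
                               int(both.sum()))


def euclidean_difference(z_a, z_b) -> tuple[np.ndarray, dict]:
    """Per-position 1-D Euclidean distance |zA - zB| (NA where either is NA)
    and a summary dict (n, mean, max)."""
    a, b = _values(z_a), _values(z_b)
    if len(a) != len(b):
        raise ValueError("profiles must have the same length")
    d = np.abs(a - b)
    ok = ~np.isnan(d)
    summary = {"n": int(ok.sum()),
               "mean": float(np.mean(d[ok])) if ok.any() else float("nan"),
               "max": float(np.max(d[ok])) if ok.any() else float("nan")}
    return d, summary


def smoothed_zdiff(z_a, z_b, window: int = 15, min_valid: int = 8,
                   threshold_sd: float = 1.0,
                   two_sided: bool = False) -> SmoothedDifference:
    """Centered moving average of the z-score difference with region calls.

    Each window mean uses the non-NA values inside it and is NA below
    ``min_valid`` contributing values (sequence ends truncate windows).
    The region threshold is ``threshold_sd`` sample SDs of the smoothed
    series; regions are maximal runs above +threshold (one-sided by default,
    mirroring positive-excursion shading; ``two_sided`` also calls runs below
    -threshold). A constant smoothed series (SD = 0) is flagged degenerate
    and yields no regions.
    """
    a, b = _values(z_a), _values(z_b)
    if len(a) != len(b):
        raise ValueError("profiles must have the same length")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = len(a)
    if window > n:
        raise ValueError("window exceeds sequence length")
    diff = a - b
    half = window // 2
    sm = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = diff[lo:hi]
        seg = seg[~np.isnan(seg)]
        if len(seg) >= min(min_valid, window):
            sm[i] = seg.mean()
    ok = ~np.isnan(sm)
    if ok.sum() >= 2:
        sd = float(np.std(sm[ok], ddof=1))
    else:
        sd = float("nan")
    degenerate = not np.isfinite(sd) or sd == 0.0
    regions: list[tuple[int, int]] = []
    if not degenerate:
        thr = threshold_sd * sd
        exceed = (sm > thr) | (two_sided & (sm < -thr))
        exceed &= ok
        start = None
        for i, e in enumerate(exceed):
            if e and start is None:
                start = i
            elif not e and start is not None:
                regions.append((start, i))
                start = None
        if start is not None:
            regions.append((start, n))
    return SmoothedDifference(sm, 0.0 if degenerate else sd, regions,
                              window, degenerate)


def ranksum_compare(values_a, values_b,
                    alternative: str = "two-sided") -> tuple[float, float]:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney U): exact null enumeration
    for small tie-free samples (both n <= 8), tie-corrected normal
    approximation otherwise. Returns (U of the first sample, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= 8 and len(b) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# structure annotation
# ---------------------------------------------------------------------------

def write_scores_to_structure(scores: Mapping[int, float],
                              structure_file: str | Path,
                              out_file: str | Path,
                              sentinel: float = -99.0) -> list[int]:
    """Write per-residue scores into the B-factor column of a PDB file.

    ``scores`` maps residue numbers (as numbered in the structure) to values;
    residues absent from the map get ``sentinel``. Returns the residue
    numbers present in the structure but missing from ``scores``.
    """
    from Bio.PDB import PDBParser, PDBIO

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(structure_file))
    missing: list[int] = []
    for residue in structure.get_residues():
        resnum = residue.id[1]
        value = scores.get(resnum)
        if value is None:
            missing.append(resnum)
            value = sentinel
        for atom in residue:
            atom.set_bfactor(float(value))
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_file))
    return missing


def read_structure_scores(structure_file: str | Path) -> dict[int, float]:
    """Read back per-residue B-factors (first atom of each residue)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(structure_file))
    out: dict[int, float] = {}
    for residue in structure.get_residues():
        atom = next(iter(residue), None)
        if atom is not None and residue.id[1] not in out:
            out[residue.id[1]] = float(atom.get_bfactor())
    return out
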
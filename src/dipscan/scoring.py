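"""Permissibility scoring: the F -> G -> z -> {0,1} ladder.

Per-position enrichment for one replicate is the difference of read
fractions between the surface-expressed (SE) and non-surface-expressed (NSE)
pools,

    F(i) = r_SE(i) / t_SE  -  r_NSE(i) / t_NSE,

defined only where both pools have reads at position i (NA otherwise).
``t`` is the pool's total productive read count, which makes F scale-free
and gives the exact zero-sum property sum_i F(i) = 0 when no position is NA.
Replicate profiles average into a mean profile G (over non-NA replicates),
which can be z-scored, trimmed of near-zero positions, and binarized
(1 = permissive) for downstream differential and model analyses.

All profiles are numpy float arrays with NaN as the NA marker, indexed by
insertion slot (0 = before residue 1).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .insertion_calling import InsertionCountTable


class EmptyPoolError(ValueError):
    """A pool with zero total reads cannot be used for enrichment."""


class DegenerateProfileError(ValueError):
    """All-NA or constant profile: z-scoring undefined."""


@dataclass
class PermissibilityProfile:
    """Per-slot enrichment F for one replicate of one domain."""

    values: np.ndarray
    replicate: int = 0
    domain: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def na_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class MeanProfile:
    """Replicate-mean permissibility G; ``n_used[i]`` counts the non-NA
    replicates behind G(i)."""

    values: np.ndarray
    n_used: np.ndarray
    domain: str = ""


@dataclass
class ZProfile:
    values: np.ndarray
    domain: str = ""


@dataclass
class BinaryProfile:
    """0 = not permissive, 1 = permissive, NaN = NA."""

    values: np.ndarray
    domain: str = ""


def enrichment(se: InsertionCountTable, nse: InsertionCountTable,
               ) -> PermissibilityProfile:
    """Eq. F: difference of pool read fractions; NA unless both pools have
    reads at the position."""
    if se.n_positions != nse.n_positions:
        raise ValueError("SE and NSE tables must cover the same positions")
    if se.t == 0 or nse.t == 0:
        raise EmptyPoolError(
            f"empty pool: t_SE={se.t}, t_NSE={nse.t}")
    f = se.counts / se.t - nse.counts / nse.t
    f[(se.counts == 0) | (nse.counts == 0)] = np.nan
    return PermissibilityProfile(f, replicate=se.replicate, domain=se.domain)


def mean_profile(profiles: Sequence[PermissibilityProfile],
                 strict: bool = False) -> MeanProfile:
    """Replicate mean G(i).

    Default: mean over replicates where F(i) is non-NA (a position missing in
    one replicate is not dragged toward 0). ``strict=True`` divides the sum
    of non-NA values by the full replicate count n instead.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    stack = np.vstack([p.values for p in profiles])
    n_used = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        if strict:
            g = np.where(n_used > 0, np.nansum(stack, axis=0) / len(profiles),
                         np.nan)
        else:
            g = np.where(n_used > 0,
                         np.nansum(stack, axis=0) / np.maximum(n_used, 1),
                         np.nan)
    return MeanProfile(g, n_used, domain=profiles[0].domain)


def zscore_profile(mean: MeanProfile | ZProfile) -> ZProfile:
    """Z-score over non-NA positions (sample SD, ddof=1); NA preserved."""
    v = np.asarray(mean.values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise DegenerateProfileError("need >= 2 scored positions to z-score")
    sd = np.std(v[ok], ddof=1)
    if sd == 0:
        raise DegenerateProfileError("constant profile cannot be z-scored")
    z = (v - np.mean(v[ok])) / sd
    return ZProfile(z, domain=getattr(mean, "domain", ""))


def trim_near_zero(values_by_dataset: Sequence[np.ndarray] | np.ndarray,
                   eps: float = 1e-4,
                   max_fraction: float = 6 / 16) -> np.ndarray:
    """Keep-mask over positions for the near-zero sampling-noise band.

    A position is kept iff the fraction of datasets whose value lies in
    (-eps, +eps) — NA counted as in-band — is at most ``max_fraction``.
    Presets used downstream: 6/16 for position/dataset correlation analyses,
    1/2 for property correlations, and per-profile (single-dataset) trimming
    before model training.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if not 0 <= max_fraction <= 1:
        raise ValueError("max_fraction must be in [0, 1]")
    arr = np.vstack(values_by_dataset).astype(float)
    in_band = np.isnan(arr) | (np.abs(arr) < eps)
    frac = in_band.mean(axis=0)
    return frac <= max_fraction + 1e-12


def binarize(profile, threshold: float = 0.0) -> BinaryProfile:
    """1 where value > threshold, 0 where <= threshold, NA preserved.
    Accepts a profile object or a bare array. Idempotent at threshold 0 on
    its own output only for positive/zero coding, which holds here."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    v = np.asarray(getattr(profile, "values", profile), dtype=float)
    out = np.where(np.isnan(v), np.nan, (v > threshold).astype(float))
    return BinaryProfile(out, domain=getattr(profile, "domain", ""))


def coverage_report(profile, n_total: int, decimals: int = 1,
                    ) -> tuple[int, int, str]:
    """(n_scored, n_total, percent string), round-half-up at ``decimals``.

    ``profile`` may be a profile object, an array (non-NA entries counted),
    or an integer count.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if isinstance(profile, (int, np.integer)):
        n_scored = int(profile)
    else:
        v = np.asarray(getattr(profile, "values", profile), dtype=float)
        n_scored = int(np.sum(~np.isnan(v)))
    if n_scored > n_total:
        raise ValueError("n_scored exceeds n_total")
    pct = decimal.Decimal(100 * n_scored) / decimal.Decimal(n_total)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    pct = pct.quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    return n_scored, n_total, f"{pct}%"


# ---------------------------------------------------------------------------
# TSV I/O (columns: aa_pos, value, na_flag, replicate, domain, pool)
# ---------------------------------------------------------------------------

def write_profile_tsv(profile, path: str | Path, pool: str = "") -> None:
    v = np.asarray(profile.values, dtype=float)
    replicate = getattr(profile, "replicate", 0)
    domain = getattr(profile, "domain", "")
    with open(path, "w") as fh:
        fh.write("# aa_pos = insertion slot (0 = before residue 1)\n")
        fh.write("aa_pos\tvalue\tna_flag\treplicate\tdomain\tpool\n")
        for i, x in enumerate(v):
            na = int(np.isnan(x))
            val = "" if na else f"{x:.10g}"
            fh.write(f"{i}\t{val}\t{na}\t{replicate}\t{domain}\t{pool}\n")


def read_profile_tsv(path: str | Path) -> PermissibilityProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    v = np.full(int(df["aa_pos"].max()) + 1, np.nan)
    ok = df["na_flag"] == 0
    v[df.loc[ok, "aa_pos"].to_numpy()] = df.loc[ok, "value"].to_numpy(float)
    first = df.iloc[0]
    return PermissibilityProfile(v, replicate=int(first.get("replicate", 0)),
                                 domain=str(first.get("domain", "")))
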
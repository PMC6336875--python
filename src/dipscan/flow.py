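"""Flow-cytometry statistics for the DiBAC resting-membrane-potential and
light-modulation assays.

Events arrive as plain tables (one row per event: scatter, marker and dye
channels plus acquisition index). The dye channel is arcsinh-transformed,
events pass a sequential gate chain (scatter rectangles, marker quantile
cut), channel function is scored as the percentage of events below the
median of a wild-type reference (the "lower 50% of WT" gate: hyperpolarized
cells take up less of the anionic voltage dye), and light modulation is the
Pearson chi-squared dissimilarity between dark and illuminated samples on a
15%-most-hyperpolarized gate derived from the dark sample, normalized for
photobleaching and averaged across K+ challenges. Variant-vs-WT inference
uses one-sided Welch t tests (function) and Dunnett many-to-one comparisons
(light modulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RectangleGate:
    """Keep events with channel values inside [lo, hi] on one or two
    channels (None = unbounded)."""

    channel: str
    bounds: tuple[float | None, float | None]
    channel2: str | None = None
    bounds2: tuple[float | None, float | None] | None = None


@dataclass(frozen=True)
class QuantileGate:
    """Keep events below/above the q-quantile of ``channel``; the cut is
    derived from ``reference`` events when given, else from the gated data
    itself."""

    channel: str
    q: float
    side: Literal["below", "above"] = "above"
    reference: object | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("quantile must be in (0, 1)")


GateSpec = Sequence[RectangleGate | QuantileGate]


def arcsinh_transform(events, cofactor: float = 150.0, channel: str = "dye"):
    """x -> asinh(x / cofactor) on the dye channel only."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    out = events.copy()
    out[channel] = np.arcsinh(out[channel] / cofactor)
    return out


def apply_gates(events, spec: GateSpec):
    """Apply gates in order; surviving events keep their order and t_acq."""
    out = events
    for gate in spec:
        if isinstance(gate, RectangleGate):
            out = _apply_rectangle(out, gate)
        elif isinstance(gate, QuantileGate):
            out = _apply_quantile(out, gate)
        else:
            raise TypeError(f"unknown gate type: {type(gate).__name__}")
    return out


def _check_channel(events, channel: str) -> None:
    if channel not in events.columns:
        raise KeyError(f"unknown channel {channel!r}")


def _apply_rectangle(events, gate: RectangleGate):
    _check_channel(events, gate.channel)
    keep = np.ones(len(events), dtype=bool)
    lo, hi = gate.bounds
    v = events[gate.channel].to_numpy()
    if lo is not None:
        keep &= v >= lo
    if hi is not None:
        keep &= v <= hi
    if gate.channel2 is not None:
        _check_channel(events, gate.channel2)
        lo2, hi2 = gate.bounds2 or (None, None)
        v2 = events[gate.channel2].to_numpy()
        if lo2 is not None:
            keep &= v2 >= lo2
        if hi2 is not None:
            keep &= v2 <= hi2
    return events[keep]


def _apply_quantile(events, gate: QuantileGate):
    _check_channel(events, gate.channel)
    source = gate.reference if gate.reference is not None else events
    _check_channel(source, gate.channel)
    cut = float(np.quantile(source[gate.channel].to_numpy(), gate.q))
    v = events[gate.channel].to_numpy()
    keep = v < cut if gate.side == "below" else v >= cut
    return events[keep]


def default_gates(reference_marker=None) -> list:
    """Scatter singlet chain plus a transfection-marker cut approximating
    the published gating scheme: whole cells on FSC-A/SSC-A, singlets on
    FSC-A vs FSC-H, then the top 60% of the marker channel (on the
    reference sample when given)."""
    return [
        RectangleGate("fsc_a", (1e4, 3e5), "ssc_a", (3e3, 3e5)),
        RectangleGate("fsc_h", (1e4, 3e5)),
        QuantileGate("marker", 0.4, side="above", reference=reference_marker),
    ]


# ---------------------------------------------------------------------------
# function score
# ---------------------------------------------------------------------------

@dataclass
class FunctionScore:
    """Percent-hyperpolarized per replicate for one variant."""

    variant: str
    percent: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.percent))

    @property
    def sd(self) -> float:
        return float(np.std(self.percent, ddof=1)) if len(self.percent) > 1 else 0.0

    @property
    def n(self) -> int:
        return len(self.percent)


def hyperpolarized_percent(variant_events, wt_events,
                           channel: str = "dye") -> float:
    """Percent of variant events strictly below the wild-type median dye
    signal (the lower-50%-of-WT gate)."""
    if len(variant_events) == 0 or len(wt_events) == 0:
        raise ValueError("event sets must be non-empty")
    threshold = float(np.median(wt_events[channel].to_numpy()))
    frac = np.mean(variant_events[channel].to_numpy() < threshold)
    return 100.0 * float(frac)


def function_test(variant_means: Sequence[float],
                  control_means: Sequence[float],
                  alternative: str = "greater") -> tuple[float, float]:
    """One-sided Welch two-sample t test on replicate-level
    percent-hyperpolarized values."""
    a = np.asarray(variant_means, float)
    b = np.asarray(control_means, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# light/dark dissimilarity
# ---------------------------------------------------------------------------

@dataclass
class LightDissimilarity:
    """Per-K+-challenge chi-squared dissimilarities and their photobleaching-
    normalized mean."""

    chi2: list[float]
    normalized: list[float]
    mean: float
    tables: list[np.ndarray] = field(default_factory=list)


def light_dissimilarity(dark, light, q: float = 0.15, channel: str = "dye",
                        direction: Literal["below", "above"] = "below",
                        ) -> tuple[float, np.ndarray]:
    """Chi-squared dissimilarity of dark vs illuminated samples.

    The gate includes the ``q`` most hyperpolarized fraction of the *dark*
    sample (lowest dye signal by default); both samples are cross-tabulated
    as [in-gate, out-gate] x [dark, light] and the Pearson statistic (no
    continuity correction) is returned with the 2x2 table
    [[dark_in, dark_out], [light_in, light_out]].
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if len(dark) == 0 or len(light) == 0:
        raise ValueError("event sets must be non-empty")
    dv = dark[channel].to_numpy()
    lv = light[channel].to_numpy()
    if direction == "below":
        cut = float(np.quantile(dv, q))
        d_in, l_in = int(np.sum(dv < cut)), int(np.sum(lv < cut))
    else:
        cut = float(np.quantile(dv, 1.0 - q))
        d_in, l_in = int(np.sum(dv >= cut)), int(np.sum(lv >= cut))
    table = np.array([[d_in, len(dv) - d_in], [l_in, len(lv) - l_in]])
    chi2 = pearson_chi2(table)
    return chi2, table


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-squared statistic of a contingency table, no continuity
    correction. Degenerate margins (an empty row/column) give 0."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    total = t.sum()
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0
    expected = rows @ cols / total
    return float(((t - expected) ** 2 / expected).sum())


def normalize_and_average(per_challenge_chi2: Sequence[float],
                          per_challenge_event_counts: Sequence[int],
                          wt_reference_chi2: Sequence[float] | None = None,
                          ) -> LightDissimilarity:
    """Photobleaching/scale normalization of per-challenge dissimilarities.

    Default: chi2 / N_total per challenge (a Cramer-style removal of the
    event-count scale, so proportional changes in acquisition size cancel);
    when matched wild-type values are given, each normalized value is further
    divided by the corresponding WT value. The mean over challenges is the
    summary statistic.
    """
    chi2 = [float(c) for c in per_challenge_chi2]
    counts = [int(n) for n in per_challenge_event_counts]
    if len(chi2) != len(counts):
        raise ValueError("chi2 and event-count lists must align")
    normalized = [c / n if n else float("nan") for c, n in zip(chi2, counts)]
    if wt_reference_chi2 is not None:
        if len(wt_reference_chi2) != len(chi2):
            raise ValueError("WT reference list must align with challenges")
        normalized = [v / w if w else float("nan")
                      for v, w in zip(normalized, wt_reference_chi2)]
    return LightDissimilarity(chi2, normalized, float(np.nanmean(normalized)))


# ---------------------------------------------------------------------------
# many-to-one inference
# ---------------------------------------------------------------------------

def many_to_one_test(variant_scores: Mapping[str, Sequence[float]],
                     wt_scores: Sequence[float],
                     method: Literal["dunnett", "bonferroni"] = "dunnett",
                     alternative: str = "two-sided"):
    """Compare each variant against the wild-type control.

    ``dunnett`` uses the equicorrelated multivariate-t distribution of the
    max statistic (pooled variance); ``bonferroni`` multiplies the pooled-
    variance two-sample t p-value by the number of comparisons — always at
    least as conservative. Returns a DataFrame indexed by variant with
    columns statistic and p_adjusted.
    """
    import pandas as pd

    control = np.asarray(wt_scores, float)
    if len(control) < 2:
        raise ValueError("control group needs >= 2 replicates")
    names = list(variant_scores)
    groups = [np.asarray(variant_scores[n], float) for n in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every variant needs >= 2 replicates")
    if method == "dunnett":
        res = stats.dunnett(*groups, control=control, alternative=alternative)
        stat = np.asarray(res.statistic, float)
        pval = np.asarray(res.pvalue, float)
    elif method == "bonferroni":
        # pooled-variance statistic matching Dunnett's, Bonferroni-adjusted
        all_groups = groups + [control]
        n_total = sum(len(g) for g in all_groups)
        df_resid = n_total - len(all_groups)
        ss = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
        s2 = ss / df_resid
        stat = np.array([
            (g.mean() - control.mean())
            / np.sqrt(s2 * (1 / len(g) + 1 / len(control)))
            for g in groups])
        if alternative == "two-sided":
            p_raw = 2 * stats.t.sf(np.abs(stat), df_resid)
        elif alternative == "greater":
            p_raw = stats.t.sf(stat, df_resid)
        else:
            p_raw = stats.t.cdf(stat, df_resid)
        pval = np.minimum(1.0, len(groups) * p_raw)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"statistic": stat, "p_adjusted": pval}, index=names)


def read_events_tsv(path) -> "object":
    import pandas as pd

    return pd.read_csv(path, sep="\t")
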